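"""DTOF interchange format: one CSV per histogram plus a JSON sidecar.

The CSV holds two columns (channel_index, counts); the sidecar of the same
basename carries channel_width_ps, t0_channel, acquisition_time_s,
wavelength_nm, geometry, kind and free-form provenance. Round trips are
bit-exact for counts and metadata; unknown sidecar keys are preserved in
``DTOF.meta``.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .forward import Geometry
from .instrument import DTOF

__all__ = ["read_dtof", "write_dtof", "FormatError"]

_SIDE_KEYS = {
    "channel_width_ps",
    "t0_channel",
    "acquisition_time_s",
    "wavelength_nm",
    "kind",
    "geometry",
}


class FormatError(ValueError):
    """Malformed or incomplete interchange files."""


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_dtof(dtof: DTOF, path) -> Path:
    """Write a DTOF as CSV + JSON sidecar; returns the CSV path."""
    path = Path(path)
    if path.suffix != ".csv":
        path = path.with_suffix(".csv")
    pd.DataFrame(
        {"channel_index": np.arange(dtof.n_channels), "counts": dtof.counts}
    ).to_csv(path, index=False)
    geo = None
    if dtof.geometry is not None:
        geo = {
            "mode": dtof.geometry.mode,
            "rho_mm": dtof.geometry.rho_mm,
            "thickness_mm": dtof.geometry.thickness_mm,
            "n_external": dtof.geometry.n_external,
        }
    side = {
        "channel_width_ps": dtof.channel_width_ps,
        "t0_channel": int(dtof.t0_channel),
        "acquisition_time_s": dtof.acquisition_time_s,
        "wavelength_nm": dtof.wavelength_nm,
        "kind": dtof.kind,
        "geometry": geo,
    }
    # extra metadata rides along; only JSON-serializable entries are kept
    for k, v in dtof.meta.items():
        try:
            json.dumps(v)
        except TypeError:
            continue
        side[k] = v
    _sidecar_path(path).write_text(json.dumps(side, indent=1))
    return path


def read_dtof(path) -> DTOF:
    """Read a DTOF from the CSV + JSON interchange pair."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"missing histogram file {path}")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing JSON sidecar {sidecar}")
    side = json.loads(sidecar.read_text())
    missing = _SIDE_KEYS - set(side)
    if missing:
        raise FormatError(f"sidecar {sidecar} missing keys {sorted(missing)}")
    df = pd.read_csv(path)
    if not {"channel_index", "counts"} <= set(df.columns):
        raise FormatError(f"{path} must have columns channel_index, counts")
    counts = df.sort_values("channel_index")["counts"].to_numpy(np.int64)
    geo = side["geometry"]
    geometry = Geometry(**geo) if geo is not None else None
    meta = {k: v for k, v in side.items() if k not in _SIDE_KEYS}
    return DTOF(
        counts=counts,
        channel_width_ps=float(side["channel_width_ps"]),
        t0_channel=int(side["t0_channel"]),
        acquisition_time_s=float(side["acquisition_time_s"]),
        wavelength_nm=float(side["wavelength_nm"]),
        geometry=geometry,
        kind=side["kind"],
        meta=meta,
    )
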