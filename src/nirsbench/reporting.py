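"""FOM bookkeeping, summary statistics and the virtual campaign driver.

A :class:`FomRecord` is one synthetic indicator value produced by one
protocol test on one instrument — the atom of the population summary
table. :func:`summarize` aggregates records into descriptive statistics
(count, mean, sample std, min, quartiles by linear interpolation, max) per
(protocol, test, fom, property) group. :func:`virtual_campaign` runs the
whole pipeline — BIP, the six MEDPHOT tests on the virtual kit, and the
depth-scan detection test — on a set of virtual instruments, deterministic
from a single seed.
"""
from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import bip as _bip
from . import medphot as _medphot
from . import neuropt as _neuropt
from .forward import Geometry, InclusionSpec, OpticalProperties
from .instrument import (
    InstrumentModel,
    medphot_kit,
    make_irf,
    synthesize_dark,
    synthesize_depth_scan,
    synthesize_dnl_measurement,
    synthesize_dtof_replicates,
    synthesize_noise_series,
    synthesize_responsivity_measurement,
    synthesize_sessions,
    synthesize_stability_series,
)
from .retrieval import FitOptions, fit_optical_properties

__all__ = [
    "FomRecord",
    "SummaryRow",
    "CampaignConfig",
    "summarize",
    "render_table",
    "virtual_campaign",
]

PROTOCOLS = ("BIP", "MEDPHOT", "NEUROPT")
PROPERTY_TAGS = ("Mua", "Mus", "All")


@dataclass(frozen=True)
class FomRecord:
    """One synthetic indicator value."""

    protocol: str
    test: str
    fom: str
    opt: str  # property tag: Mua, Mus or All
    value: float
    units: str
    instrument: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.protocol not in PROTOCOLS:
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if self.opt not in PROPERTY_TAGS:
            raise ValueError(f"unknown property tag {self.opt!r}")
        if not np.isfinite(self.value):
            raise ValueError(f"FOM value must be finite, got {self.value!r}")


@dataclass(frozen=True)
class SummaryRow:
    """Descriptive statistics of one FOM over the instrument population."""

    count: int
    mean: float
    std: float
    min: float
    p25: float
    p50: float
    p75: float
    max: float
    degenerate: bool = False  # single record: std reported as 0

    @classmethod
    def from_values(cls, values: np.ndarray) -> "SummaryRow":
        x = np.asarray(values, dtype=float)
        degenerate = x.size < 2
        p25, p50, p75 = np.percentile(x, [25, 50, 75])  # linear interpolation
        return cls(
            count=int(x.size),
            mean=float(x.mean()),
            std=0.0 if degenerate else float(np.std(x, ddof=1)),
            min=float(x.min()),
            p25=float(p25),
            p50=float(p50),
            p75=float(p75),
            max=float(x.max()),
            degenerate=degenerate,
        )


def records_frame(records) -> pd.DataFrame:
    rows = [asdict(r) if isinstance(r, FomRecord) else dict(r) for r in records]
    return pd.DataFrame(rows)


def summarize(records) -> pd.DataFrame:
    """Summary statistics per (protocol, test, fom, opt) group.

    Accepts a list of FomRecord or a compatible DataFrame. Empty groups are
    impossible by construction; single-record groups report std = 0 with
    the ``degenerate`` flag set.
    """
    df = records if isinstance(records, pd.DataFrame) else records_frame(records)
    if df.empty:
        warnings.warn("no records to summarize", UserWarning, stacklevel=2)
        return pd.DataFrame()
    out = []
    for (protocol, test, fom, opt), sub in df.groupby(
        ["protocol", "test", "fom", "opt"], sort=False
    ):
        row = SummaryRow.from_values(sub["value"].to_numpy())
        units = sub["units"].iloc[0]
        out.append(
            {
                "protocol": protocol,
                "test": test,
                "unit": units,
                "fom": fom,
                "opt": opt,
                **asdict(row),
            }
        )
    return pd.DataFrame(out)


def render_table(summary: pd.DataFrame) -> str:
    """Plain-text population summary table."""
    cols = ["protocol", "test", "unit", "fom", "opt",
            "count", "mean", "std", "min", "p25", "p50", "p75", "max"]
    df = summary[cols].copy()
    for c in ("mean", "std", "min", "p25", "p50", "p75", "max"):
        df[c] = df[c].map(lambda v: f"{v:.4g}")
    return df.to_string(index=False)


# ---------------------------------------------------------------------------
# Virtual campaign
# ---------------------------------------------------------------------------


@dataclass
class CampaignConfig:
    """Conditions of a virtual multi-instrument exercise.

    Defaults reproduce the standard protocol conditions: 1-s acquisitions
    at a 5e5 counts/s target rate, 20 repetitions, reference phantom B2 for
    the single-phantom tests, B3 for the accuracy comparison, a >= 1 h
    stability run, three measurement sessions, and a depth scan of the
    equivalent dmua = 0.17 cm^-1 / 1 cm^3 inclusion in a 0.1/10 cm^-1
    background.
    """

    instruments: list[InstrumentModel] | None = None
    modalities: list[str] | None = None  # "TD" (default) or "CW" per instrument
    geometry: Geometry = field(default_factory=Geometry)
    signal_counts: float = 5e5
    n_reps: int = 20
    kit_labels: list[str] | None = None  # None = full 32-phantom kit
    accuracy_label: str = "B3"
    reference_label: str = "B2"
    noise_levels: tuple[float, ...] = (3e4, 1e5, 3e5, 1e6, 3e6)
    stability_duration_min: float = 60.0
    stability_period_s: float = 300.0
    n_sessions: int = 3
    depth_scan_depths: tuple[float, ...] = tuple(np.arange(4.0, 31.0, 2.0))
    inclusion: InclusionSpec = field(default_factory=lambda: InclusionSpec(depth_mm=15.0))
    irf_counts: float = 1e6
    dnl_counts_per_channel: float = 1e5
    dark_tmeas_s: float = 10.0
    true_responsivity_m2sr: float = 1.2e-8
    kappa_p: float = 8.3e16
    Pin_W: float = 1e-3
    # campaign-level analyses pin t0 from the IRF so timing defects propagate
    fit_options: FitOptions = field(default_factory=lambda: FitOptions(fit_t0=False))

    def config_hash(self) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if hasattr(o, "__dict__"):
                return vars(o)
            return str(o)

        blob = json.dumps(asdict(self), default=default, sort_keys=True)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


def _fit_many(dtofs, irf, geometry, options):
    return [fit_optical_properties(d, irf, geometry, options) for d in dtofs]


def _mean_props(fits) -> tuple[float, float]:
    return (
        float(np.mean([f.props.mua for f in fits])),
        float(np.mean([f.props.musp for f in fits])),
    )


def virtual_campaign(
    n_instruments: int = 3,
    seed: int = 0,
    config: CampaignConfig | None = None,
) -> tuple[list[FomRecord], pd.DataFrame]:
    """Run the full protocol suite on a population of virtual instruments.

    Returns (records, summary). Instruments default to ``n_instruments``
    identical defect-free instruments (the null campaign). Time-domain
    instruments undergo all tests; CW-like instruments only the total-count
    detection test, mirroring the applicability matrix of a real exercise.
    """
    cfg = config or CampaignConfig()
    instruments = cfg.instruments or [
        InstrumentModel.ideal() for _ in range(n_instruments)
    ]
    modalities = cfg.modalities or ["TD"] * len(instruments)
    if len(modalities) != len(instruments):
        raise ValueError("one modality per instrument required")

    kit = medphot_kit()
    if cfg.kit_labels is not None:
        kit = [p for p in kit if p.label in set(cfg.kit_labels)]
    ref_phantom = next(p for p in medphot_kit() if p.label == cfg.reference_label)
    acc_phantom = next(p for p in medphot_kit() if p.label == cfg.accuracy_label)

    prov_base = {"seed": seed, "config": cfg.config_hash()}
    root = np.random.SeedSequence(seed)
    inst_seqs = root.spawn(len(instruments))

    records: list[FomRecord] = []
    acc_estimates: dict[str, tuple[float, float]] = {}

    def rec(protocol, test, fom, opt, value, units, inst_id, **extra):
        records.append(
            FomRecord(protocol, test, fom, opt, float(value), units, inst_id,
                      provenance={**prov_base, **extra})
        )

    for idx, (instr, modality, seq) in enumerate(zip(instruments, modalities, inst_seqs)):
        inst_id = f"VI{idx + 1:02d}"
        (s_irf, s_resp, s_dnl, s_dark, s_kit, s_stab, s_noise, s_sess, s_scan) = seq.spawn(9)

        if modality == "TD":
            # ---- BIP ----
            irf_dtof = make_irf(instr.irf, instr, cfg.irf_counts,
                                seed=int(s_irf.generate_state(1)[0] % 2**31))
            rec("BIP", "IRF", "FWHM", "All", _bip.irf_fwhm(irf_dtof), "ps", inst_id)
            resp_in = synthesize_responsivity_measurement(
                instr, cfg.kappa_p, cfg.Pin_W, 1.0, cfg.true_responsivity_m2sr,
                seed=int(s_resp.generate_state(1)[0] % 2**31))
            rec("BIP", "Responsivity", "Responsivity", "All",
                _bip.responsivity(resp_in), "m^2 sr", inst_id)
            dnl_hist = synthesize_dnl_measurement(
                instr, cfg.dnl_counts_per_channel,
                seed=int(s_dnl.generate_state(1)[0] % 2**31))
            rec("BIP", "DNL", "DNL", "All", _bip.dnl_eps(dnl_hist), "-", inst_id)
            dark = synthesize_dark(instr, cfg.dark_tmeas_s,
                                   seed=int(s_dark.generate_state(1)[0] % 2**31))
            rec("BIP", "DarkCounts", "Dark counts", "All",
                _bip.dark_count_rate(dark), "counts/s", inst_id)

            # ---- MEDPHOT: kit (accuracy source, linearity, crosstalk) ----
            rows = []
            for phantom, p_seq in zip(kit, s_kit.spawn(len(kit))):
                reps = synthesize_dtof_replicates(
                    phantom.nominal, cfg.geometry, instr, cfg.n_reps,
                    signal_counts=cfg.signal_counts, seed=p_seq)
                fits = _fit_many(reps, irf_dtof, cfg.geometry, cfg.fit_options)
                mua, mus = _mean_props(fits)
                rows.append({
                    "label": phantom.label,
                    "nominal_mua": phantom.nominal.mua,
                    "nominal_mus": phantom.nominal.musp,
                    "mua": mua, "mus": mus,
                    "mua_sd": float(np.std([f.props.mua for f in fits], ddof=1)),
                    "mus_sd": float(np.std([f.props.musp for f in fits], ddof=1)),
                })
            kitm = _medphot.KitMeasurement(records=pd.DataFrame(rows), n_reps=cfg.n_reps)
            lin_mua, lin_mus = _medphot.linearity_fom(kitm)
            rec("MEDPHOT", "Linearity", "Linearity", "Mua", lin_mua, "%", inst_id)
            rec("MEDPHOT", "Linearity", "Linearity", "Mus", lin_mus, "%", inst_id)
            xt = _medphot.crosstalk_fom(kitm)
            rec("MEDPHOT", "Linearity", "Crosstalk", "Mua", xt.F_mus_to_mua, "-", inst_id)
            rec("MEDPHOT", "Linearity", "Crosstalk", "Mus", xt.F_mua_to_mus, "-", inst_id)
            acc_row = kitm.records[kitm.records["label"] == cfg.accuracy_label]
            if not acc_row.empty:
                acc_estimates[inst_id] = (
                    float(acc_row["mua"].iloc[0]), float(acc_row["mus"].iloc[0]))
            else:
                reps = synthesize_dtof_replicates(
                    acc_phantom.nominal, cfg.geometry, instr, cfg.n_reps,
                    signal_counts=cfg.signal_counts, seed=s_kit.spawn(len(kit) + 1)[-1])
                fits = _fit_many(reps, irf_dtof, cfg.geometry, cfg.fit_options)
                acc_estimates[inst_id] = _mean_props(fits)

            # ---- MEDPHOT: stability ----
            minutes, series = synthesize_stability_series(
                ref_phantom.nominal, instr,
                duration_min=cfg.stability_duration_min,
                period_s=cfg.stability_period_s,
                n_reps=cfg.n_reps,
                geometry=cfg.geometry, signal_counts=cfg.signal_counts,
                seed=int(s_stab.generate_state(1)[0] % 2**31))
            point_fits = [
                _fit_many(reps, irf_dtof, cfg.geometry, cfg.fit_options)
                for reps in series
            ]
            for prop, tag in (("mua", "Mua"), ("musp", "Mus")):
                vals = [np.mean([getattr(f.props, prop) for f in fits])
                        for fits in point_fits]
                st = _medphot.stability_fom(minutes, vals)
                rec("MEDPHOT", "Stability", "Range", tag, st.range_pct, "%", inst_id)
                rec("MEDPHOT", "Stability", "Drift", tag, st.drift_pct_per_min,
                    "%/min", inst_id)

            # ---- MEDPHOT: noise ----
            noise_opts = FitOptions(
                fit_t0=cfg.fit_options.fit_t0,
                counts_floor=min(cfg.fit_options.counts_floor, min(cfg.noise_levels) / 2),
            )
            series_by_level = synthesize_noise_series(
                ref_phantom.nominal, instr, list(cfg.noise_levels),
                n_reps=cfg.n_reps, geometry=cfg.geometry,
                seed=int(s_noise.generate_state(1)[0] % 2**31))
            est_mua, est_mus = [], []
            for level in cfg.noise_levels:
                fits = _fit_many(series_by_level[level], irf_dtof, cfg.geometry, noise_opts)
                est_mua.append([f.props.mua for f in fits])
                est_mus.append([f.props.musp for f in fits])
            rec("MEDPHOT", "Noise", "Counts1%", "Mua",
                _medphot.noise_fom(cfg.noise_levels, est_mua), "counts", inst_id)
            rec("MEDPHOT", "Noise", "Counts1%", "Mus",
                _medphot.noise_fom(cfg.noise_levels, est_mus), "counts", inst_id)

            # ---- MEDPHOT: reproducibility ----
            sessions = synthesize_sessions(
                ref_phantom.nominal, instr, n_sessions=cfg.n_sessions,
                n_reps=cfg.n_reps, geometry=cfg.geometry,
                signal_counts=cfg.signal_counts,
                seed=int(s_sess.generate_state(1)[0] % 2**31))
            means_mua, means_mus = [], []
            for sess in sessions:
                fits = _fit_many(sess, irf_dtof, cfg.geometry, cfg.fit_options)
                mua, mus = _mean_props(fits)
                means_mua.append(mua)
                means_mus.append(mus)
            rec("MEDPHOT", "Reproducibility", "Reproducibility", "Mua",
                _medphot.reproducibility_fom(means_mua), "%", inst_id)
            rec("MEDPHOT", "Reproducibility", "Reproducibility", "Mus",
                _medphot.reproducibility_fom(means_mus), "%", inst_id)

        # ---- nEUROPt detection (TD: late window; CW: total counts) ----
        scan = synthesize_depth_scan(
            instr, np.asarray(cfg.depth_scan_depths), cfg.inclusion,
            geometry=cfg.geometry, n_reps=cfg.n_reps,
            signal_counts=cfg.signal_counts,
            seed=int(s_scan.generate_state(1)[0] % 2**31))
        if modality == "TD":
            profile = _neuropt.depth_profile(scan)
            fom = _neuropt.neuropt_fom(profile, depth_mm=20.0, window="late")
        else:
            profile = _neuropt.cw_contrast(scan)
            fom = _neuropt.neuropt_fom(profile, depth_mm=20.0, window="cw")
        rec("NEUROPT", "Detection", "Contrast", "All", fom.contrast_abs, "-",
            inst_id, window=fom.window, depth_mm=fom.depth_used_mm)
        rec("NEUROPT", "Detection", "CNR", "All", fom.cnr_abs, "-",
            inst_id, window=fom.window, depth_mm=fom.depth_used_mm)

    # ---- population accuracy (deviation around the median) ----
    if len(acc_estimates) >= 3:
        ids = list(acc_estimates)
        mua_arr = np.array([acc_estimates[i][0] for i in ids])
        mus_arr = np.array([acc_estimates[i][1] for i in ids])
        for arr, tag in ((mua_arr, "Mua"), (mus_arr, "Mus")):
            res = _medphot.accuracy_deviation(arr)
            for inst_id, dev in zip(ids, res.deviations_pct):
                rec("MEDPHOT", "Accuracy", "Deviation", tag, dev, "%", inst_id)
    elif acc_estimates:
        warnings.warn("accuracy FOM needs >= 3 instruments; skipped",
                      UserWarning, stacklevel=2)

    return records, summarize(records)
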