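"""Basic instrument performance (BIP) figures of merit.

Four hardware-level descriptors of a time-domain photon-counting system:

* IRF FWHM (ps) — temporal resolution of the whole detection chain;
* responsivity (m^2 sr) — detected counts per unit photon radiance exiting
  a calibrated diffusive slab: s = Ntot / (tmeas * kappa_p * Pin);
* differential nonlinearity — peak-to-peak non-uniformity of the TCSPC
  channel widths relative to the mean, from a flat-light histogram;
* dark count rate (counts/s) — total background with the source removed.
"""
from __future__ import annotations

import numpy as np

from .instrument import DTOF, ResponsivityInputs

__all__ = ["irf_fwhm", "responsivity", "dnl_eps", "dark_count_rate", "ResponsivityInputs"]


def irf_fwhm(irf: DTOF) -> float:
    """Full width at half maximum of an IRF histogram, in ps.

    The flat background (median of the lowest decile of channel counts) is
    subtracted first; each half-maximum crossing is located by linear
    interpolation between the adjacent channels.
    """
    y = irf.counts.astype(float)
    n = y.size
    n_bg = max(n // 10, 1)
    background = float(np.median(np.sort(y)[:n_bg]))
    y = y - background
    peak_idx = int(np.argmax(y))
    peak = y[peak_idx]
    if peak <= 0:
        raise ValueError("IRF histogram has no peak above background")
    half = 0.5 * peak

    def _cross(idx_lo: int, idx_hi: int) -> float:
        # linear interpolation of the crossing between two adjacent channels
        y0, y1 = y[idx_lo], y[idx_hi]
        return idx_lo + (half - y0) / (y1 - y0)

    left = np.nonzero(y[: peak_idx + 1] < half)[0]
    if left.size == 0:
        raise ValueError("IRF truncated: no half-maximum crossing on the rising flank")
    i = int(left[-1])
    x_left = _cross(i, i + 1)

    right = np.nonzero(y[peak_idx:] < half)[0]
    if right.size == 0:
        raise ValueError("IRF truncated: no half-maximum crossing on the falling flank")
    j = peak_idx + int(right[0])
    x_right = _cross(j - 1, j)

    return float((x_right - x_left) * irf.channel_width_ps)


def responsivity(inp: ResponsivityInputs) -> float:
    """Detection responsivity in m^2 sr: Ntot / (tmeas * kappa_p * Pin)."""
    return inp.Ntot / (inp.tmeas_s * inp.kappa_p * inp.Pin_W)


def dnl_eps(hist: DTOF, edge_exclude_frac: float = 0.02) -> float:
    """Differential nonlinearity: (max - min) / mean over the active range.

    The first and last ``edge_exclude_frac`` of channels are excluded
    (edge artifacts of the timing electronics).
    """
    y = hist.counts.astype(float)
    k = int(round(edge_exclude_frac * y.size))
    active = y[k : y.size - k] if k > 0 else y
    if active.size == 0:
        raise ValueError("active range is empty")
    mean = active.mean()
    if mean == 0:
        raise ValueError("mean count is zero over the active range")
    return float((active.max() - active.min()) / mean)


def dark_count_rate(dark: DTOF) -> float:
    """Dark count rate in counts/s from a dark measurement."""
    if dark.kind != "dark":
        raise ValueError(f"expected a dark measurement, got kind={dark.kind!r}")
    if dark.acquisition_time_s <= 0:
        raise ValueError("acquisition_time_s must be > 0")
    return dark.total_counts / dark.acquisition_time_s
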