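"""Inhomogeneity-detection figures of merit: time-windowed contrast and
contrast-to-noise ratio (CNR) over a depth scan of an absorbing inclusion.

Contrast at inclusion position i:   C_i = (M_i - M_0) / M_0
Contrast-to-noise ratio:            CNR_i = (M_i - M_0) / sigma(M_0)

where M is the photon count in a time window (400-ps windows by default;
"early" = [400, 800) ps, "late" = [2000, 2400) ps after the time origin),
M_0 and sigma(M_0) come from the repeated homogeneous baseline acquisitions,
and M_i is averaged over the repetitions at position i. For continuous-wave
operation the same definitions apply to the total counts (a single
full-span window). The synthetic indicators are the magnitudes of contrast
and CNR in the late window with the inclusion at 20 mm depth.

The time origin for the windows defaults to the nominal grid origin (the
IRF peak channel of the producing instrument); it can be overridden.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .instrument import DTOF, DepthScan

__all__ = [
    "TimeWindow",
    "EARLY",
    "LATE",
    "ContrastProfile",
    "NeuroptFom",
    "window_counts",
    "contrast",
    "cnr",
    "depth_profile",
    "neuropt_fom",
    "cw_contrast",
]


@dataclass(frozen=True)
class TimeWindow:
    """Half-open time window [t_start, t_end) relative to the time origin."""

    t_start_ps: float
    t_end_ps: float
    name: str = ""

    def __post_init__(self) -> None:
        if not self.t_end_ps > self.t_start_ps:
            raise ValueError("t_end_ps must exceed t_start_ps")

    @property
    def width_ps(self) -> float:
        return self.t_end_ps - self.t_start_ps


EARLY = TimeWindow(400.0, 800.0, name="early")
LATE = TimeWindow(2000.0, 2400.0, name="late")


@dataclass
class ContrastProfile:
    """Per-depth, per-window contrast and CNR of a depth scan."""

    depths_mm: np.ndarray
    windows: tuple[TimeWindow, ...]
    contrast: np.ndarray  # (n_depths, n_windows)
    cnr: np.ndarray  # (n_depths, n_windows)
    Mi: np.ndarray  # (n_depths, n_windows) mean window counts at position
    M0: np.ndarray  # (n_windows,) baseline mean
    sigma_M0: np.ndarray  # (n_windows,) baseline std (n-1)

    def window_index(self, window) -> int:
        if isinstance(window, int):
            return window
        for i, w in enumerate(self.windows):
            if w is window or (isinstance(window, str) and w.name == window):
                return i
        raise KeyError(f"window {window!r} not in profile")


@dataclass(frozen=True)
class NeuroptFom:
    """Detection-test synthetic indicators: |contrast| and |CNR| at the
    selected (depth, window); depth_used_mm records the actual profile
    depth if no scanned position was within 1 mm of the request."""

    contrast_abs: float
    cnr_abs: float
    depth_used_mm: float
    window: str


def window_counts(dtof: DTOF, window: TimeWindow, t_ref_ps: float = 0.0) -> float:
    """Counts in [t_ref + t_start, t_ref + t_end), fractional at the edges.

    Channel contents are treated as uniform within each channel, so edge
    channels contribute proportionally to their overlap with the window.
    """
    dt = dtof.channel_width_ps
    centers = dtof.times_ps
    lo = t_ref_ps + window.t_start_ps
    hi = t_ref_ps + window.t_end_ps
    span_lo = centers[0] - dt / 2.0
    span_hi = centers[-1] + dt / 2.0
    if lo < span_lo - 1e-9 or hi > span_hi + 1e-9:
        raise ValueError("time window extends outside the histogram span")
    left = np.clip((np.minimum(hi, centers + dt / 2.0) - np.maximum(lo, centers - dt / 2.0)) / dt,
                   0.0, 1.0)
    return float(np.sum(dtof.counts * left))


def contrast(Mi: float, M0: float) -> float:
    """Relative count change (M_i - M_0) / M_0."""
    if M0 == 0:
        raise ValueError("baseline window count M0 is zero")
    return (Mi - M0) / M0


def cnr(Mi: float, M0_reps) -> float:
    """Contrast-to-noise ratio against repeated baseline acquisitions."""
    reps = np.asarray(M0_reps, dtype=float)
    if reps.size < 2:
        raise ValueError("CNR needs >= 2 baseline repetitions")
    sd = np.std(reps, ddof=1)
    if sd == 0:
        raise ValueError("baseline standard deviation is zero")
    return float((Mi - reps.mean()) / sd)


def depth_profile(
    scan: DepthScan,
    windows: tuple[TimeWindow, ...] = (EARLY, LATE),
    t_ref_ps: float = 0.0,
) -> ContrastProfile:
    """Contrast and CNR per depth and time window for a full depth scan.

    M_i averages the window counts over the repetitions at each position;
    M_0 and sigma(M_0) are the mean and sample standard deviation of the
    baseline repetitions.
    """
    if len(scan.baseline) < 2:
        raise ValueError("depth profile needs >= 2 baseline repetitions")
    n_w = len(windows)
    m0_reps = np.array(
        [[window_counts(b, w, t_ref_ps) for w in windows] for b in scan.baseline]
    )  # (n_reps, n_w)
    M0 = m0_reps.mean(axis=0)
    sigma = np.std(m0_reps, ddof=1, axis=0)
    if np.any(M0 == 0):
        raise ValueError("baseline window count M0 is zero")
    if np.any(sigma == 0):
        raise ValueError("baseline standard deviation is zero")

    n_d = scan.depths_mm.size
    Mi = np.empty((n_d, n_w))
    for i, reps in enumerate(scan.dtofs):
        vals = np.array([[window_counts(r, w, t_ref_ps) for w in windows] for r in reps])
        Mi[i] = vals.mean(axis=0)

    C = (Mi - M0) / M0
    R = (Mi - M0) / sigma
    return ContrastProfile(
        depths_mm=scan.depths_mm,
        windows=tuple(windows),
        contrast=C,
        cnr=R,
        Mi=Mi,
        M0=M0,
        sigma_M0=sigma,
    )


def neuropt_fom(
    profile: ContrastProfile, depth_mm: float = 20.0, window="late"
) -> NeuroptFom:
    """Magnitudes of contrast and CNR at the selected depth and window.

    The nearest scanned depth is used; if it is more than 1 mm from the
    request this is visible through ``depth_used_mm``.
    """
    j = profile.window_index(window)
    i = int(np.argmin(np.abs(profile.depths_mm - depth_mm)))
    return NeuroptFom(
        contrast_abs=float(abs(profile.contrast[i, j])),
        cnr_abs=float(abs(profile.cnr[i, j])),
        depth_used_mm=float(profile.depths_mm[i]),
        window=profile.windows[j].name or str(j),
    )


def cw_contrast(scan: DepthScan) -> ContrastProfile:
    """Contrast/CNR from total counts (continuous-wave equivalent).

    Identical to :func:`depth_profile` with a single window spanning the
    whole histogram.
    """
    ref = scan.baseline[0]
    dt = ref.channel_width_ps
    lo = ref.times_ps[0] - dt / 2.0
    hi = ref.times_ps[-1] + dt / 2.0
    full = TimeWindow(lo, hi, name="cw")
    return depth_profile(scan, windows=(full,), t_ref_ps=0.0)
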