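"""MEDPHOT figures of merit: accuracy, linearity, crosstalk, stability,
noise and day-to-day reproducibility of retrieved optical properties.

All indicators operate on retrieved (mua, musp) values; none of them
requires "conventionally true" phantom properties. Accuracy is defined
against the population median; linearity and crosstalk regress retrieved
properties against the nominal kit grid (the series' design variable);
noise interpolates the coefficient of variation versus total counts in
log-log space; all coefficients of variation use the sample (n-1)
standard deviation.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "KitMeasurement",
    "CrosstalkResult",
    "AccuracyResult",
    "StabilityResult",
    "accuracy_deviation",
    "linearity_fom",
    "crosstalk_fom",
    "coupling_effect_pct",
    "stability_fom",
    "drift_projection",
    "cv",
    "noise_fom",
    "reproducibility_fom",
]

#: reference optical properties the relative coupling coefficients refer to
MUA0_CM1 = 0.1
MUS0_CM1 = 10.0


@dataclass
class KitMeasurement:
    """Retrieved properties over (a subset of) the homogeneous kit.

    ``records`` is a DataFrame with columns
    label, nominal_mua, nominal_mus, mua, mus [, mua_sd, mus_sd];
    one row per phantom; values are the means over the repetitions.
    """

    records: pd.DataFrame
    wavelength_nm: float = 830.0
    n_reps: int = 20

    REQUIRED = ("label", "nominal_mua", "nominal_mus", "mua", "mus")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise ValueError(f"KitMeasurement records missing columns {missing}")

    @property
    def letters(self) -> pd.Series:
        return self.records["label"].str[0]

    @property
    def digits(self) -> pd.Series:
        return self.records["label"].str[1:]


@dataclass(frozen=True)
class CrosstalkResult:
    """Crosstalk slopes and relative coupling coefficients.

    Naming is cause -> effect: ``F_mua_to_mus`` quantifies how a relative
    change in absorption leaks into the retrieved scattering, and
    vice versa. S values are median absolute regression slopes of the
    affected retrieved property versus the nominal varied property.
    """

    S_mus_given_mua: float
    S_mua_given_mus: float
    F_mua_to_mus: float
    F_mus_to_mua: float
    mua0: float = MUA0_CM1
    mus0: float = MUS0_CM1


@dataclass(frozen=True)
class AccuracyResult:
    deviations_pct: np.ndarray
    median_pct: float


@dataclass(frozen=True)
class StabilityResult:
    range_pct: float
    drift_pct_per_min: float


def accuracy_deviation(estimates) -> AccuracyResult:
    """Per-instrument relative deviation around the population median, %.

    ``estimates`` is one retrieved property (mua or musp) per instrument at
    a common wavelength, over >= 3 instruments. The summary indicator is the
    median of the per-instrument deviations.
    """
    x = np.asarray(estimates, dtype=float)
    if x.size < 3:
        raise ValueError("accuracy needs estimates from >= 3 instruments")
    med = float(np.median(x))
    if med == 0:
        raise ValueError("population median is zero")
    dev = np.abs(x - med) / abs(med) * 100.0
    return AccuracyResult(deviations_pct=dev, median_pct=float(np.median(dev)))


def _series_groups(kit: KitMeasurement, vary: str):
    """Yield (series_id, nominal x, retrieved y) per constant-property series."""
    df = kit.records
    if vary == "mua":
        group_key, x_col, y_col = kit.letters, "nominal_mua", "mua"
    else:
        group_key, x_col, y_col = kit.digits, "nominal_mus", "mus"
    for gid, sub in df.groupby(group_key):
        yield gid, sub[x_col].to_numpy(float), sub[y_col].to_numpy(float)


def _valid_series(x: np.ndarray) -> bool:
    return np.unique(x).size >= 3


def linearity_fom(kit: KitMeasurement) -> tuple[float, float]:
    """Median relative deviation from the per-series linear fit, % (mua, musp).

    Per constant-scattering series, retrieved mua is regressed on nominal
    mua (OLS); each point contributes |y - yhat| / |yhat| * 100; the FOM is
    the median over all points of all series. Symmetric for musp within
    constant-absorption series. Degenerate series are skipped with a warning.
    """
    out = []
    for vary in ("mua", "mus"):
        devs = []
        for gid, x, y in _series_groups(kit, vary):
            if not _valid_series(x):
                warnings.warn(f"series {gid!r} degenerate for {vary} linearity; skipped",
                              UserWarning, stacklevel=2)
                continue
            slope, intercept = np.polyfit(x, y, 1)
            yhat = slope * x + intercept
            ok = np.abs(yhat) > 1e-12
            devs.extend((np.abs(y - yhat) / np.abs(yhat) * 100.0)[ok])
        if not devs:
            raise ValueError(f"no usable series for {vary} linearity")
        out.append(float(np.median(devs)))
    return out[0], out[1]


def crosstalk_fom(
    kit: KitMeasurement, mua0: float = MUA0_CM1, mus0: float = MUS0_CM1
) -> CrosstalkResult:
    """Relative coupling coefficients between the two optical properties.

    Within each constant-absorption series the retrieved mua is regressed on
    the nominal musp; the median absolute slope S_mua_given_mus, rescaled by
    the reference ratio mus0/mua0, gives the scattering-to-absorption
    coupling F_mus_to_mua (and symmetrically for the other direction). A
    coupling F with a relative cause increment d% produces an F*d% relative
    effect on the affected property.
    """
    slopes_mua = []  # retrieved mua vs nominal musp, per digit series
    for gid, sub in kit.records.groupby(kit.digits):
        x = sub["nominal_mus"].to_numpy(float)
        y = sub["mua"].to_numpy(float)
        if not _valid_series(x):
            warnings.warn(f"series digit {gid!r} degenerate for crosstalk; skipped",
                          UserWarning, stacklevel=2)
            continue
        slopes_mua.append(np.polyfit(x, y, 1)[0])
    slopes_mus = []  # retrieved musp vs nominal mua, per letter series
    for gid, sub in kit.records.groupby(kit.letters):
        x = sub["nominal_mua"].to_numpy(float)
        y = sub["mus"].to_numpy(float)
        if not _valid_series(x):
            warnings.warn(f"series letter {gid!r} degenerate for crosstalk; skipped",
                          UserWarning, stacklevel=2)
            continue
        slopes_mus.append(np.polyfit(x, y, 1)[0])
    if not slopes_mua or not slopes_mus:
        raise ValueError("no usable series for crosstalk")
    S_mua_given_mus = float(np.median(np.abs(slopes_mua)))
    S_mus_given_mua = float(np.median(np.abs(slopes_mus)))
    return CrosstalkResult(
        S_mus_given_mua=S_mus_given_mua,
        S_mua_given_mus=S_mua_given_mus,
        F_mua_to_mus=S_mus_given_mua * mua0 / mus0,
        F_mus_to_mua=S_mua_given_mus * mus0 / mua0,
        mua0=mua0,
        mus0=mus0,
    )


def coupling_effect_pct(F: float, cause_pct: float) -> float:
    """Relative effect (%) on the affected property for a relative cause change.

    E.g. F = 0.13 with a 10% cause increment yields a 1.3% effect.
    """
    return F * cause_pct


def stability_fom(times_min, values) -> StabilityResult:
    """Stability indicators of a time series of one retrieved property.

    range = (max - min)/mean * 100; drift = |OLS slope vs time| / mean * 100
    per minute. The protocol expects >= 10 points spanning >= 60 min
    (a warning is raised otherwise).
    """
    t = np.asarray(times_min, dtype=float)
    x = np.asarray(values, dtype=float)
    if t.size != x.size:
        raise ValueError("times and values must have equal length")
    if t.size < 10 or (t.max() - t.min()) < 60.0:
        warnings.warn("stability series shorter than the protocol's 10 points / 60 min",
                      UserWarning, stacklevel=2)
    mean = x.mean()
    if mean == 0:
        raise ValueError("series mean is zero")
    rng_pct = (x.max() - x.min()) / abs(mean) * 100.0
    slope = np.polyfit(t, x, 1)[0]
    return StabilityResult(
        range_pct=float(rng_pct),
        drift_pct_per_min=float(abs(slope) / abs(mean) * 100.0),
    )


def drift_projection(drift_pct_per_min: float, minutes: float) -> float:
    """Projected deviation (%) accumulated by a constant drift over `minutes`."""
    if minutes < 0:
        raise ValueError("minutes must be >= 0")
    return drift_pct_per_min * minutes


def cv(values) -> float:
    """Coefficient of variation in %: sample (n-1) std over the mean."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("cv needs >= 2 values")
    mean = x.mean()
    if mean == 0:
        raise ValueError("mean is zero")
    return float(np.std(x, ddof=1) / abs(mean) * 100.0)


def noise_fom(count_levels, estimates_per_level) -> float:
    """Total counts needed for a 1% coefficient of variation.

    Fits log10(CV%) versus log10(N) by OLS over the measured count levels
    (>= 3 levels spanning >= 1 decade) and returns the count total where the
    fitted line crosses CV = 1%. The fitted slope must be negative.
    """
    levels = np.asarray(count_levels, dtype=float)
    if levels.size < 3:
        raise ValueError("noise test needs >= 3 count levels")
    if levels.max() / levels.min() < 10.0:
        warnings.warn("count levels span less than a decade", UserWarning, stacklevel=2)
    cvs = np.array([cv(est) for est in estimates_per_level])
    if np.any(cvs <= 0):
        raise ValueError("non-positive CV encountered")
    slope, intercept = np.polyfit(np.log10(levels), np.log10(cvs), 1)
    if slope >= 0:
        raise ValueError("degenerate noise fit: CV does not decrease with counts")
    # solve slope * log10(N) + intercept = log10(1%) = 0
    return float(10.0 ** (-intercept / slope))


def reproducibility_fom(session_means) -> float:
    """Between-session CV (%) of a retrieved property over >= 2 sessions."""
    return cv(session_means)
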