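"""Virtual TD-NIRS instrument and virtual phantom kits.

This is the synthetic-data generator of the package: it produces TCSPC
photon time-of-flight histograms (DTOFs) with the statistical structure the
protocol tests assume — diffusion-theory signal shapes convolved with a
parametric instrument response function (IRF), uniform dark counts, static
differential-nonlinearity (DNL) channel-width modulation, slow drifts,
session-to-session jitter, and Poisson counting noise.

Standard conditions are built in as defaults: 1-s acquisitions at a target
signal rate of 5e5 counts/s, repeated 20 times, on reference phantoms with
(mua, musp) = (0.05..0.1, 10) cm^-1.

All stochastic operations are reproducible from (seed, parameters);
repetitions draw from sub-streams spawned via ``numpy.random.SeedSequence``.
Every generated DTOF carries its pre-sampling channel expectation so that
oracle tests can compare sampled histograms against exact means.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .forward import (
    Geometry,
    InclusionSpec,
    OpticalProperties,
    td_perturbed_reflectance,
    td_reflectance,
    td_transmittance,
)

__all__ = [
    "IRFModel",
    "InstrumentModel",
    "PhantomSpec",
    "DTOF",
    "DepthScan",
    "ResponsivityInputs",
    "medphot_kit",
    "make_irf",
    "synthesize_dtof",
    "synthesize_dtof_replicates",
    "synthesize_stability_series",
    "synthesize_noise_series",
    "synthesize_sessions",
    "synthesize_dnl_measurement",
    "synthesize_dark",
    "synthesize_depth_scan",
    "synthesize_responsivity_measurement",
    "convolve_irf",
]

# MEDPHOT kit grid: letters index the scattering series, digits the
# absorption steps (convention anchored on B2 = (0.05, 10) cm^-1 and
# B3 = (0.1, 10) cm^-1; not claimed to match the physical kit's engraving).
_KIT_LETTERS = {"A": 5.0, "B": 10.0, "C": 15.0, "D": 20.0}
_KIT_DIGITS = {str(d): 0.05 * (d - 1) for d in range(1, 9)}


@dataclass(frozen=True)
class IRFModel:
    """Parametric IRF: Gaussian core plus single exponential tail.

    ``tail_fraction`` of the area sits in a one-sided exponential decay of
    time constant ``tail_tau_ps`` starting at the Gaussian center — the
    qualitative signature of silicon (SPAD/SiPM) detectors; hybrid PMT or
    MCP detectors are emulated with tail_fraction ~ 0.
    """

    fwhm_ps: float = 300.0
    tail_fraction: float = 0.0
    tail_tau_ps: float = 500.0
    t0_ps: float = 0.0

    def __post_init__(self) -> None:
        if self.fwhm_ps <= 0:
            raise ValueError("fwhm_ps must be > 0")
        if not 0 <= self.tail_fraction < 1:
            raise ValueError("tail_fraction must lie in [0, 1)")
        if self.tail_tau_ps <= 0:
            raise ValueError("tail_tau_ps must be > 0")

    def density(self, t_ps: np.ndarray) -> np.ndarray:
        """Normalized IRF density (ps^-1) on an arbitrary time axis."""
        t = np.asarray(t_ps, dtype=float) - self.t0_ps
        sigma = self.fwhm_ps / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        core = np.exp(-0.5 * (t / sigma) ** 2) / (sigma * np.sqrt(2.0 * np.pi))
        out = (1.0 - self.tail_fraction) * core
        if self.tail_fraction > 0:
            tail = np.where(t >= 0, np.exp(-np.clip(t, 0, None) / self.tail_tau_ps), 0.0)
            out = out + self.tail_fraction * tail / self.tail_tau_ps
        return out


@dataclass(frozen=True)
class InstrumentModel:
    """Virtual-instrument description driving the synthetic generator.

    dnl_pattern holds per-channel relative width multipliers with mean 1;
    drift terms are linear in elapsed time; session_jitter is the fractional
    day-to-day perturbation of amplitude and timing (t0 scale = jitter x
    IRF FWHM).
    """

    irf: IRFModel = field(default_factory=IRFModel)
    channel_width_ps: float = 10.0
    n_channels: int = 1024
    t0_channel: int = 128
    dark_rate_cps: float = 0.0
    dnl_pattern: np.ndarray | None = None
    drift_amp_per_min: float = 0.0
    drift_t0_ps_per_min: float = 0.0
    session_jitter: float = 0.0

    def __post_init__(self) -> None:
        if self.channel_width_ps <= 0:
            raise ValueError("channel_width_ps must be > 0")
        if self.n_channels < 16:
            raise ValueError("n_channels must be >= 16")
        if self.dark_rate_cps < 0:
            raise ValueError("dark_rate_cps must be >= 0")
        if self.dnl_pattern is not None:
            pat = np.asarray(self.dnl_pattern, dtype=float)
            if pat.shape != (self.n_channels,):
                raise ValueError("dnl_pattern length must equal n_channels")
            if np.any(pat <= 0):
                raise ValueError("dnl_pattern entries must be > 0")
            if abs(pat.mean() - 1.0) > 1e-9:
                raise ValueError("dnl_pattern mean must be 1 within 1e-9")
            object.__setattr__(self, "dnl_pattern", pat)

    @property
    def channel_times_ps(self) -> np.ndarray:
        """Channel-center times relative to the nominal time origin."""
        return (np.arange(self.n_channels) - self.t0_channel) * self.channel_width_ps

    def dnl(self) -> np.ndarray:
        if self.dnl_pattern is None:
            return np.ones(self.n_channels)
        return self.dnl_pattern

    @classmethod
    def ideal(cls, channel_width_ps: float = 10.0, n_channels: int = 1024) -> "InstrumentModel":
        """Defect-free instrument: delta-like IRF, no dark/DNL/drift/jitter."""
        return cls(
            irf=IRFModel(fwhm_ps=channel_width_ps, tail_fraction=0.0),
            channel_width_ps=channel_width_ps,
            n_channels=n_channels,
            t0_channel=n_channels // 8,
        )


@dataclass(frozen=True)
class PhantomSpec:
    """One phantom of the homogeneous kit: label plus nominal properties at 800 nm."""

    label: str
    nominal: OpticalProperties


@dataclass
class DTOF:
    """Photon time-of-flight histogram with channel grid and acquisition metadata.

    ``expectation`` holds the pre-sampling per-channel Poisson mean when the
    histogram was produced by the generator (None for external data).
    """

    counts: np.ndarray
    channel_width_ps: float
    t0_channel: int
    acquisition_time_s: float
    wavelength_nm: float = 830.0
    geometry: Geometry | None = None
    kind: str = "measurement"
    expectation: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if not np.issubdtype(c.dtype, np.integer):
            if not np.allclose(c, np.rint(c)):
                raise ValueError("counts must be integral")
            c = np.rint(c).astype(np.int64)
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        self.counts = c.astype(np.int64)
        if self.kind not in ("measurement", "irf", "dark", "dnl"):
            raise ValueError(f"unknown DTOF kind {self.kind!r}")

    @property
    def n_channels(self) -> int:
        return self.counts.size

    @property
    def times_ps(self) -> np.ndarray:
        """Channel-center times relative to the nominal time origin, ps."""
        return (np.arange(self.n_channels) - self.t0_channel) * self.channel_width_ps

    @property
    def total_counts(self) -> int:
        return int(self.counts.sum())


@dataclass
class DepthScan:
    """Inclusion-position-indexed DTOF sets plus homogeneous baseline reps."""

    depths_mm: np.ndarray
    dtofs: list  # list (per depth) of lists of DTOF
    baseline: list  # repeated homogeneous DTOFs
    n_reps: int

    def __post_init__(self) -> None:
        self.depths_mm = np.asarray(self.depths_mm, dtype=float)
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2")
        if not self.baseline:
            raise ValueError("baseline must be non-empty")
        if len(self.dtofs) != self.depths_mm.size:
            raise ValueError("one DTOF list per depth required")


@dataclass(frozen=True)
class ResponsivityInputs:
    """Inputs of the responsivity formula: s = Ntot / (tmeas * kappa_p * Pin)."""

    Ntot: float
    tmeas_s: float
    kappa_p: float
    Pin_W: float

    def __post_init__(self) -> None:
        if self.Ntot < 0:
            raise ValueError("Ntot must be >= 0")
        for name in ("tmeas_s", "kappa_p", "Pin_W"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def medphot_kit(wavelength_nm: float = 800.0, n_medium: float = 1.55) -> list[PhantomSpec]:
    """The full 32-phantom homogeneous kit.

    8 absorption steps (mua = 0 .. 0.35 cm^-1 in steps of 0.05, digits 1-8)
    x 4 scattering levels (musp = 5, 10, 15, 20 cm^-1, letters A-D), nominal
    at 800 nm.
    """
    kit = []
    for letter, musp in _KIT_LETTERS.items():
        for digit, mua in _KIT_DIGITS.items():
            kit.append(
                PhantomSpec(
                    label=f"{letter}{digit}",
                    nominal=OpticalProperties(mua=round(mua, 10), musp=musp, n_medium=n_medium),
                )
            )
    return kit


def kit_phantom(label: str, **kw) -> PhantomSpec:
    """Look up a single kit phantom by its label (e.g. "B2")."""
    for p in medphot_kit(**kw):
        if p.label == label:
            return p
    raise KeyError(f"no phantom {label!r} in the kit")


# ---------------------------------------------------------------------------
# IRF and convolution machinery
# ---------------------------------------------------------------------------

def _irf_curve(instrument: InstrumentModel) -> np.ndarray:
    """IRF expectation shape on the instrument channel grid (sums to ~1)."""
    t = instrument.channel_times_ps
    dens = instrument.irf.density(t)
    return dens * instrument.channel_width_ps


def make_irf(
    irf_model: IRFModel,
    instrument: InstrumentModel,
    total_counts: float = 1e6,
    acquisition_time_s: float = 1.0,
    seed: int | None = None,
) -> DTOF:
    """Synthesize an IRF measurement histogram.

    Returns the deterministic expectation curve rounded to integers when
    ``seed`` is None, or a Poisson sample of it otherwise.
    """
    if irf_model.fwhm_ps < instrument.channel_width_ps / 2.0:
        raise ValueError(
            "IRF FWHM below half the channel width cannot be resolved "
            f"({irf_model.fwhm_ps} ps vs {instrument.channel_width_ps} ps channels)"
        )
    t = instrument.channel_times_ps
    curve = irf_model.density(t) * instrument.channel_width_ps
    area = curve.sum()
    if area < 0.999:
        raise ValueError("acquisition window contains < 99.9% of the IRF area")
    expectation = curve / area * total_counts
    if seed is None:
        counts = np.rint(expectation)
    else:
        counts = np.random.default_rng(seed).poisson(expectation)
    return DTOF(
        counts=counts,
        channel_width_ps=instrument.channel_width_ps,
        t0_channel=instrument.t0_channel,
        acquisition_time_s=acquisition_time_s,
        kind="irf",
        expectation=expectation,
        meta={"fwhm_ps_model": irf_model.fwhm_ps},
    )


def convolve_irf(
    model_samples: np.ndarray,
    irf_curve: np.ndarray,
    t0_channel: int,
    trim_rtol: float = 1e-12,
) -> np.ndarray:
    """Convolve forward-model channel samples with a measured/modelled IRF.

    Both arrays live on the same channel grid whose time origin sits at
    index ``t0_channel`` (of the IRF array). The kernel is trimmed to its
    numerically relevant support and normalized to unit sum, so the output
    preserves the total of ``model_samples`` up to edge truncation.
    """
    w = np.asarray(irf_curve, dtype=float)
    n = model_samples.size
    nz = np.nonzero(w > w.max() * trim_rtol)[0]
    if nz.size == 0:
        raise ValueError("IRF curve is identically zero")
    s, e = nz[0], nz[-1] + 1
    kern = w[s:e]
    kern = kern / kern.sum()
    full = np.convolve(model_samples, kern)
    start = t0_channel - s
    out = np.zeros(n)
    lo = max(start, 0)
    hi = min(start + n, full.size)
    if hi > lo:
        out[lo - start : lo - start + (hi - lo)] = full[lo:hi]
    return out


def expected_dtof_shape(
    props: OpticalProperties,
    geometry: Geometry,
    instrument: InstrumentModel,
    t0_shift_ps: float = 0.0,
) -> np.ndarray:
    """Unnormalized expected signal shape: forward model (x) IRF on channels."""
    t = instrument.channel_times_ps
    if geometry.mode == "reflectance":
        fwd = td_reflectance(geometry.rho_mm, t, props, geometry)
    else:
        fwd = td_transmittance(t, props, geometry)
    shape = convolve_irf(fwd, _irf_curve(instrument), instrument.t0_channel)
    if t0_shift_ps:
        idx = np.arange(shape.size, dtype=float)
        shape = np.interp(idx - t0_shift_ps / instrument.channel_width_ps, idx, shape,
                          left=0.0, right=0.0)
    return shape


def _expectation(
    props: OpticalProperties,
    geometry: Geometry,
    instrument: InstrumentModel,
    signal_counts: float,
    acquisition_time_s: float,
    amp_factor: float = 1.0,
    t0_shift_ps: float = 0.0,
) -> np.ndarray:
    shape = expected_dtof_shape(props, geometry, instrument, t0_shift_ps=t0_shift_ps)
    total = shape.sum()
    if total <= 0:
        raise RuntimeError("forward model produced an empty expectation")
    sig = shape / total * signal_counts * amp_factor
    dark = instrument.dark_rate_cps * acquisition_time_s / instrument.n_channels
    lam = (sig + dark) * instrument.dnl()
    if not np.isfinite(lam).all() or np.any(lam < 0):
        raise RuntimeError("invalid channel expectation")
    return lam


def _sample(lam: np.ndarray, rng: np.random.Generator | None) -> np.ndarray:
    if rng is None:
        return np.rint(lam)
    return rng.poisson(lam)


def synthesize_dtof(
    props: OpticalProperties,
    geometry: Geometry,
    instrument: InstrumentModel,
    signal_counts: float = 5e5,
    acquisition_time_s: float = 1.0,
    wavelength_nm: float = 830.0,
    seed: int | None = 0,
    amp_factor: float = 1.0,
    t0_shift_ps: float = 0.0,
) -> DTOF:
    """Synthesize one measurement DTOF.

    The channel expectation is the IRF-convolved forward model scaled to
    ``signal_counts`` total signal, plus a uniform dark-count floor, each
    channel multiplied by its DNL width factor, then Poisson-sampled.
    A fixed seed gives bit-identical output; ``seed=None`` returns the
    rounded expectation (noise-free).
    """
    if signal_counts <= 0:
        raise ValueError("signal_counts must be > 0")
    lam = _expectation(
        props, geometry, instrument, signal_counts, acquisition_time_s,
        amp_factor=amp_factor, t0_shift_ps=t0_shift_ps,
    )
    rng = None if seed is None else np.random.default_rng(seed)
    counts = _sample(lam, rng)
    return DTOF(
        counts=counts,
        channel_width_ps=instrument.channel_width_ps,
        t0_channel=instrument.t0_channel,
        acquisition_time_s=acquisition_time_s,
        wavelength_nm=wavelength_nm,
        geometry=geometry,
        kind="measurement",
        expectation=lam,
        meta={"signal_counts": signal_counts, "seed": seed},
    )


def synthesize_dtof_replicates(
    props: OpticalProperties,
    geometry: Geometry,
    instrument: InstrumentModel,
    n_reps: int,
    signal_counts: float = 5e5,
    acquisition_time_s: float = 1.0,
    wavelength_nm: float = 830.0,
    seed: int | None = 0,
    amp_factor: float = 1.0,
    t0_shift_ps: float = 0.0,
) -> list[DTOF]:
    """n_reps independent Poisson samples of one shared channel expectation.

    Sub-streams are spawned from ``seed`` so replicates are independent yet
    reproducible; the expectation is computed once (it is identical across
    repetitions of the same acquisition).
    """
    lam = _expectation(
        props, geometry, instrument, signal_counts, acquisition_time_s,
        amp_factor=amp_factor, t0_shift_ps=t0_shift_ps,
    )
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seqs = root.spawn(n_reps)
    out = []
    for i, sq in enumerate(seqs):
        counts = np.random.default_rng(sq).poisson(lam)
        out.append(
            DTOF(
                counts=counts,
                channel_width_ps=instrument.channel_width_ps,
                t0_channel=instrument.t0_channel,
                acquisition_time_s=acquisition_time_s,
                wavelength_nm=wavelength_nm,
                geometry=geometry,
                kind="measurement",
                expectation=lam,
                meta={"rep": i, "seed": seed},
            )
        )
    return out


def synthesize_stability_series(
    props: OpticalProperties,
    instrument: InstrumentModel,
    duration_min: float = 60.0,
    period_s: float = 300.0,
    n_reps: int = 20,
    geometry: Geometry | None = None,
    signal_counts: float = 5e5,
    seed: int | None = 0,
) -> tuple[np.ndarray, list[list[DTOF]]]:
    """Time-stamped acquisition series with linear amplitude and t0 drift.

    Each time point holds ``n_reps`` repeated 1-s acquisitions (the standard
    measurement is the average of 20 repetitions). Returns
    (elapsed minutes, per-point DTOF lists); the series length is
    floor(duration/period) + 1. Durations below 60 min deviate from the
    protocol and raise a warning.
    """
    if duration_min < 60:
        warnings.warn("stability series shorter than 60 min (protocol deviation)",
                      UserWarning, stacklevel=2)
    geometry = geometry or Geometry()
    n_pts = int(np.floor(duration_min * 60.0 / period_s)) + 1
    minutes = np.arange(n_pts) * period_s / 60.0
    seqs = np.random.SeedSequence(seed).spawn(n_pts)
    dtofs = []
    for m, sq in zip(minutes, seqs):
        lam = _expectation(
            props, geometry, instrument, signal_counts, 1.0,
            amp_factor=1.0 + instrument.drift_amp_per_min * m,
            t0_shift_ps=instrument.drift_t0_ps_per_min * m,
        )
        reps = []
        for r, rq in enumerate(sq.spawn(n_reps)):
            counts = np.random.default_rng(rq).poisson(lam)
            reps.append(
                DTOF(
                    counts=counts,
                    channel_width_ps=instrument.channel_width_ps,
                    t0_channel=instrument.t0_channel,
                    acquisition_time_s=1.0,
                    geometry=geometry,
                    expectation=lam,
                    meta={"elapsed_min": float(m), "rep": r},
                )
            )
        dtofs.append(reps)
    return minutes, dtofs


def synthesize_noise_series(
    props: OpticalProperties,
    instrument: InstrumentModel,
    count_levels: list[float],
    n_reps: int = 20,
    geometry: Geometry | None = None,
    seed: int | None = 0,
) -> dict[float, list[DTOF]]:
    """Repeated 1-s acquisitions at several total-count levels."""
    geometry = geometry or Geometry()
    seqs = np.random.SeedSequence(seed).spawn(len(count_levels))
    out: dict[float, list[DTOF]] = {}
    for level, sq in zip(count_levels, seqs):
        out[level] = synthesize_dtof_replicates(
            props, geometry, instrument, n_reps, signal_counts=level, seed=sq,
        )
    return out


def synthesize_sessions(
    props: OpticalProperties,
    instrument: InstrumentModel,
    n_sessions: int = 3,
    n_reps: int = 20,
    geometry: Geometry | None = None,
    signal_counts: float = 5e5,
    seed: int | None = 0,
) -> list[list[DTOF]]:
    """Per-session DTOF sets with day-to-day amplitude and timing jitter.

    Each session draws an amplitude multiplier 1 + j*N(0,1) and a timing
    offset j*FWHM*N(0,1), with j = instrument.session_jitter.
    """
    geometry = geometry or Geometry()
    root = np.random.SeedSequence(seed)
    sess_seqs = root.spawn(n_sessions)
    out = []
    for sq in sess_seqs:
        rng = np.random.default_rng(sq)
        j = instrument.session_jitter
        amp = max(1.0 + j * rng.standard_normal(), 1e-3)
        t0s = j * instrument.irf.fwhm_ps * rng.standard_normal()
        lam = _expectation(props, geometry, instrument, signal_counts, 1.0,
                           amp_factor=amp, t0_shift_ps=t0s)
        reps = []
        for r in range(n_reps):
            counts = rng.poisson(lam)
            reps.append(
                DTOF(
                    counts=counts,
                    channel_width_ps=instrument.channel_width_ps,
                    t0_channel=instrument.t0_channel,
                    acquisition_time_s=1.0,
                    geometry=geometry,
                    expectation=lam,
                    meta={"rep": r, "session_amp": amp, "session_t0_ps": t0s},
                )
            )
        out.append(reps)
    return out


def synthesize_dnl_measurement(
    instrument: InstrumentModel,
    counts_per_channel: float = 1e5,
    seed: int | None = 0,
) -> DTOF:
    """Flat-light (CW) illumination histogram exposing the DNL pattern.

    Expectation is exactly proportional to the instrument's channel-width
    pattern; the protocol asks for >= 1e5 counts per channel.
    """
    if counts_per_channel < 1e5:
        warnings.warn("fewer than 1e5 counts per channel gives a noisy DNL estimate",
                      UserWarning, stacklevel=2)
    lam = counts_per_channel * instrument.dnl()
    rng = None if seed is None else np.random.default_rng(seed)
    counts = _sample(lam, rng)
    return DTOF(
        counts=counts,
        channel_width_ps=instrument.channel_width_ps,
        t0_channel=instrument.t0_channel,
        acquisition_time_s=1.0,
        kind="dnl",
        expectation=lam,
    )


def synthesize_dark(
    instrument: InstrumentModel,
    tmeas_s: float = 10.0,
    seed: int | None = 0,
) -> DTOF:
    """Dark measurement (laser off): uniform dark-count expectation."""
    if tmeas_s <= 0:
        raise ValueError("tmeas_s must be > 0")
    lam = np.full(instrument.n_channels,
                  instrument.dark_rate_cps * tmeas_s / instrument.n_channels)
    rng = None if seed is None else np.random.default_rng(seed)
    counts = _sample(lam, rng)
    return DTOF(
        counts=counts,
        channel_width_ps=instrument.channel_width_ps,
        t0_channel=instrument.t0_channel,
        acquisition_time_s=tmeas_s,
        kind="dark",
        expectation=lam,
    )


def synthesize_depth_scan(
    instrument: InstrumentModel,
    depths_mm: np.ndarray,
    inclusion: InclusionSpec | None = None,
    background: OpticalProperties | None = None,
    geometry: Geometry | None = None,
    n_reps: int = 20,
    signal_counts: float = 5e5,
    seed: int | None = 0,
) -> DepthScan:
    """Depth scan of the switchable inhomogeneous phantom.

    The absorbing inclusion (default equivalent dmua = 0.17 cm^-1 over
    1 cm^3) slides to each requested depth below the source-detector
    midpoint; ``n_reps`` Poisson repetitions are drawn per position plus a
    homogeneous baseline set. The baseline sets the count normalization so
    perturbed totals fall below baseline totals in expectation.
    """
    background = background or OpticalProperties(mua=0.1, musp=10.0)
    geometry = geometry or Geometry()
    depths = np.asarray(depths_mm, dtype=float)
    t = instrument.channel_times_ps
    irf_curve = _irf_curve(instrument)

    base_fwd = td_reflectance(geometry.rho_mm, t, background, geometry)
    base_shape = convolve_irf(base_fwd, irf_curve, instrument.t0_channel)
    scale = signal_counts / base_shape.sum()
    dark = instrument.dark_rate_cps * 1.0 / instrument.n_channels
    dnl = instrument.dnl()

    root = np.random.SeedSequence(seed)
    base_seq, *depth_seqs = root.spawn(1 + depths.size)

    def _make_reps(lam: np.ndarray, seq, extra_meta) -> list[DTOF]:
        reps = []
        for i, sq in enumerate(seq.spawn(n_reps)):
            counts = np.random.default_rng(sq).poisson(lam)
            reps.append(
                DTOF(
                    counts=counts,
                    channel_width_ps=instrument.channel_width_ps,
                    t0_channel=instrument.t0_channel,
                    acquisition_time_s=1.0,
                    geometry=geometry,
                    expectation=lam,
                    meta={"rep": i, **extra_meta},
                )
            )
        return reps

    lam_base = (base_shape * scale + dark) * dnl
    baseline = _make_reps(lam_base, base_seq, {"state": "baseline"})

    per_depth = []
    base_inclusion = inclusion or InclusionSpec(depth_mm=float(depths[0]))
    for d, seq in zip(depths, depth_seqs):
        inc = replace(base_inclusion, depth_mm=float(d))
        fwd = td_perturbed_reflectance(geometry.rho_mm, t, background, inc, geometry)
        shape = convolve_irf(fwd, irf_curve, instrument.t0_channel)
        lam = (shape * scale + dark) * dnl
        per_depth.append(_make_reps(lam, seq, {"state": "inclusion", "depth_mm": float(d)}))

    return DepthScan(depths_mm=depths, dtofs=per_depth, baseline=baseline, n_reps=n_reps)


def synthesize_responsivity_measurement(
    instrument: InstrumentModel,
    kappa_p: float = 8.3e16,
    Pin_W: float = 1e-3,
    tmeas_s: float = 1.0,
    true_responsivity: float = 1.2e-8,
    seed: int | None = 0,
) -> ResponsivityInputs:
    """Round-trip fixture for the responsivity formula.

    Samples the background-subtracted total count Poisson-distributed around
    ``true_responsivity * tmeas * kappa_p * Pin``. Defaults give ~1e6 counts
    for a mid-range detection chain (responsivity 1.2e-8 m^2 sr).
    """
    if Pin_W <= 0 or kappa_p <= 0 or tmeas_s <= 0:
        raise ValueError("kappa_p, Pin_W and tmeas_s must be > 0")
    expected = true_responsivity * tmeas_s * kappa_p * Pin_W
    if seed is None:
        ntot = expected
    else:
        ntot = float(np.random.default_rng(seed).poisson(expected))
    return ResponsivityInputs(Ntot=ntot, tmeas_s=tmeas_s, kappa_p=kappa_p, Pin_W=Pin_W)
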