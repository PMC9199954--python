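# Methods

`nirsbench` implements, end to end and at desk scale, the performance
assessment of time-domain near-infrared spectroscopy (TD-NIRS) instruments:
a photon-migration forward model, a virtual instrument + virtual phantom
kits that stand in for the physical reference phantoms, a canonical
optical-property retrieval, and the figures of merit (FOMs) of the three
consolidated protocol families — basic instrument performance (BIP),
homogeneous-property tests (MEDPHOT) and inhomogeneity detection (nEUROPt).
This note records the models, the defaults and why, and what the synthetic
pipeline does and does not demonstrate.

## Forward model

Photon transport is described by the diffusion approximation to the
radiative transport equation in a homogeneous medium with absorption `mua`
(cm^-1), reduced scattering `musp` (cm^-1) and refractive index `n`.

* Diffusion coefficient `D = 1/(3 musp)` (absorption-independent), photon
  speed `v = c/n` with `c = 0.0299792458 cm/ps`.
* **Boundary condition.** Extrapolated boundary: the fluence vanishes on a
  plane `z_b = 2AD` outside the surface. The internal-reflection factor `A`
  is a polynomial fit to the angular integral of the Fresnel coefficients
  in the relative index `n_medium/n_external` (A(1) = 1; A(1.4) ~ 3.0).
* **Source model.** The pencil beam is replaced by an isotropic point
  source at depth `z0 = 1/musp`, mirrored in the extrapolated boundary
  (dipole). Slab transmittance uses the standard image-source series,
  truncated when a new image pair's peak contribution falls below 1e-9 of
  the running sum's peak.
* Semi-infinite reflectance and slab transmittance are evaluated as the
  Fick flux across the physical surface; outputs are per injected photon,
  cm^-2 ps^-1. Because `D` excludes `mua`, both solutions factorize exactly
  as `model(t; mua) = model(t; 0) * exp(-mua v t)` — used as a
  machine-precision invariant in the tests.

Internal units are cm and ps. Public interfaces use mm for geometry and
cm^-1 for optical properties, the field's customary units. Defaults:
`n_medium = 1.55` (epoxy-resin phantoms; the value is not critical and is
configurable), `n_external = 1.0`, source-detector separation 30 mm in
reflectance.

### Absorbing inclusion (Born perturbation)

A small absorbing inclusion is reduced to a point perturbation of strength
`delta_mua x volume` (default 0.17 cm^-1 x 1 cm^3, the equivalent
absorption change of the black cylinder in the switchable solid phantom) at
depth `z_p` below the source-detector midpoint. First-order perturbation
theory gives

    dR(t) = -v dmua V  ∫0^t  phi(r_s -> r_p, t')  R(r_p -> r_d, t - t') dt',

the time convolution of the photon-density Green's function (source to
inclusion, with its image) and the exitance Green's function (inclusion to
detector, dipole). Both kernels are sums of terms `tau^-p exp(-a/tau)`
whose time convolution has a closed form via Laplace transforms
(`L{tau^-3/2 e^(-a/tau)} = sqrt(pi/a) e^(-2 sqrt(as))`); the production
path evaluates this closed form, which is exact, strictly linear in
`dmua x V` and preserves the Beer-Lambert factorization. A uniform-grid
trapezoid quadrature of the same integral is kept as
`method="quadrature"` and serves as an independent numerical cross-check
in the tests (the closed form was additionally verified against a
4-million-point reference integration). When the first-order term exceeds
the unperturbed signal anywhere, the perturbative regime is violated; a
`BornRegimeWarning` is raised and the result is clipped at zero. This
happens routinely for the standard inclusion at depths of a few mm —
early-window contrasts there should be read as qualitative.

The cylinder geometry of the physical inclusion is not resolved; the
point-perturbation reduction is justified by the same equivalent-`dmua`
calibration that defines the phantom.

## Virtual instrument and synthetic data

The generator emulates a TCSPC acquisition chain:

* **IRF**: Gaussian core (FWHM `fwhm_ps`) plus an area-fraction
  exponential tail (`tail_fraction`, `tail_tau_ps`) — the qualitative
  signature of silicon detectors; hybrid PMT/MCP chains are emulated with
  a negligible tail. Default FWHM 300 ps (mid-range of reported systems).
* **Histogram formation**: expectation = (forward model ⊛ IRF) on the
  channel grid (default 1024 channels x 10 ps), scaled to the target
  signal counts, plus a uniform dark-count floor
  (`dark_rate_cps x t_meas / n_channels`), each channel multiplied by its
  static DNL width factor (mean-1 multiplicative pattern), then
  Poisson-sampled. Every DTOF carries its pre-sampling expectation so
  oracle tests can compare against exact means.
* **Standard conditions** are defaults throughout: 1-s acquisitions at a
  target rate of 5e5 counts/s, repeated 20 times; reference phantom B2
  (0.05, 10 cm^-1) for single-phantom tests and B3 (0.1, 10 cm^-1) for the
  accuracy comparison; three measurement sessions; a >= 1 h stability run;
  >= 1e5 counts/channel for the DNL measurement.
* **Virtual kit**: the full 8 x 4 grid, `mua` 0..0.35 cm^-1 in 0.05 steps
  (digits 1-8) by `musp` 5..20 cm^-1 in steps of 5 (letters A-D), nominal
  at 800 nm. The letter/digit convention is anchored on B2/B3 and is a
  bookkeeping choice, not a claim about the physical kit's engraving.
* **Defect knobs**: linear amplitude and timing drift per minute
  (stability), session-to-session jitter of amplitude and timing
  (reproducibility; the timing scale is jitter x IRF FWHM), injected DNL
  patterns, dark rate. Each knob moves exactly one protocol FOM at first
  order, which the null-campaign tests exploit.
* **Reproducibility**: every stochastic operation takes a seed;
  repetitions, sessions, depths and instruments draw from
  `numpy.random.SeedSequence` spawn trees, so campaigns are bit-identical
  under a fixed seed.
* The stability series emits 20 repetitions per time point and analyses
  average the retrieved properties per point, mirroring the standard
  20-repetition measurement; a single-acquisition series is available via
  `n_reps=1`.

What the generator does **not** emulate: afterpulsing, pile-up and
count-rate nonlinearity, ambient-light structure in the dark signal,
wavelength-dependent spectra, model mismatch between data and analysis
(the same diffusion model generates and fits), and inter-laboratory
analysis diversity. Passing tests therefore demonstrate the correctness
and statistical behavior of the *analysis chain* under controlled
conditions — not that any physical instrument meets a given FOM.

## Retrieval

`(mua, musp)` are estimated by minimizing the Poisson deviance between the
measured histogram and `amplitude x (diffusion model ⊛ measured IRF)`.
The amplitude is profiled analytically (`A* = sum(y)/sum(s)` over the fit
range), making the estimate shape-only and count-scale invariant. The
timing offset `t0` is a free parameter by default; the protocol-level
analyses pin it from the IRF peak instead, so that timing defects (drift,
session jitter) propagate into the retrieved properties as they do for
real instruments whose time origin is calibrated from a separately
measured IRF.

* Fit range: from the 80%-of-peak crossing on the rising edge to the
  1%-of-peak crossing on the tail. The thresholds are located on a
  9-channel moving-average-smoothed copy of the histogram; without this
  the data-driven range jitters at low counts and inflates the CV of the
  estimates above the `N^-1/2` photon-noise law. The raw counts are always
  what is fitted.
* Bounds `mua` in [0, 2], `musp` in (0.5, 100] cm^-1; bounded L-BFGS-B
  with a two-point multi-start on the absorption axis; a solution at a
  bound clears the `converged` flag.
* Monte-Carlo checks: the fit reaches the Cramer-Rao bound for its fit
  range (CV(mua) ~ 0.4% at 1e6 counts on B2), and the CV of retrieved
  properties scales as `N^-1/2` (log-log slope -0.5 +/- 0.05 over
  1e4-1e7 counts).

## Figures of merit

* **BIP** — IRF FWHM (half-maximum crossings by linear interpolation,
  after subtracting the median of the lowest count decile as background);
  responsivity `Ntot / (tmeas kappa_p Pin)` in m^2 sr; DNL
  `(max - min)/mean` over the active channels (first/last 2% excluded by
  default); dark count rate = total counts / acquisition time.
* **MEDPHOT** — accuracy: per-instrument relative deviation around the
  population median (no "conventionally true" phantom values are assumed,
  and none are claimed); linearity: median relative deviation from
  per-series OLS lines of retrieved vs nominal grid values; crosstalk:
  median absolute OLS slope of the affected property vs the nominal varied
  property, rescaled to relative coupling coefficients with reference
  properties (0.1, 10) cm^-1 — coefficients are named cause -> effect
  (`F_mus_to_mua` = scattering-to-absorption); stability: range
  `(max-min)/mean` and drift `|OLS slope|/mean` per minute; noise: OLS in
  log10(CV%) vs log10(counts), solved at CV = 1% (log-log, since the CV
  follows a power law); reproducibility: between-session CV. All CVs use
  the sample (n-1) standard deviation.
* **nEUROPt** — counts in 400-ps time windows (early [400, 800) ps, late
  [2000, 2400) ps after the time origin, which defaults to the IRF peak
  channel); contrast `(Mi - M0)/M0` and CNR `(Mi - M0)/sigma(M0)` against
  the repeated homogeneous baseline, with `Mi` averaged over the 20
  repetitions per position; edge channels apportion counts fractionally.
  The synthetic indicators are the magnitudes at the late window and 20 mm
  depth. CW-mode contrast uses a single full-span window.

Regressions against the *nominal* grid values treat the kit coordinate as
the design variable; regressing against retrieved values instead is a
configuration choice left to the caller by constructing the kit table
accordingly.

## Virtual campaign and summary statistics

`virtual_campaign` runs the full applicability matrix (TD instruments: all
tests; CW-like instruments: total-count detection only) over a set of
virtual instruments, deterministic from one seed, and aggregates the
resulting FOM records into population summary rows (count, mean, sample
std, min, quartiles by linear interpolation, max). Problem sizes used by
the shipped acceptance study: 3 identical defect-free instruments, the
full 32-phantom kit with 20 repetitions per phantom, a 60-min stability
run sampled every 5 min, five noise levels 3e4-3e6, three sessions, and a
4-30 mm depth scan in 2-mm steps — about 2,800 fits, a few minutes on one
CPU. Null-campaign bounds verified by the test suite: linearity < 2%,
coupling coefficients < 0.05, stability range < 1%, reproducibility
CV < 0.5%, and detection FOMs statistically indistinguishable from zero on
a null scan.

## Numerical choices and degenerate inputs

* Image-source series truncation 1e-9 (relative, peak-normalized).
* Born closed form clips round-off negatives of the (non-negative)
  convolution kernel; `dmua = 0` returns the homogeneous solution
  bit-identically.
* Deviance terms with `y = 0` use the exact limit `2m`; model channels at
  exactly zero are floored at 1e-300 to keep the objective finite.
* Degenerate regression series (all nominal values equal) are skipped with
  a warning; a zero population median (accuracy), zero baseline window
  count or zero baseline spread (CNR), and a non-decreasing CV-vs-counts
  fit are hard errors rather than silent NaNs.
* Percentiles use linear interpolation between closest ranks; other
  conventions would shift population quartiles by a fraction of the
  inter-instrument spacing, so cross-study comparisons should check the
  convention first.
* Single-record summary groups report std = 0 with a `degenerate` flag.

## Known limitations

* One canonical diffusion variant is implemented; method-of-moments,
  Monte-Carlo-library, multi-distance and frequency-domain retrievals are
  out of scope, so the spread real exercises observe between analysis
  methods cannot be reproduced, only the spread induced by instrument
  models.
* The Born model is first order: contrasts for shallow or strong
  perturbations saturate in reality but scale linearly here (and are
  clipped when the regime breaks).
* The depth scan parameterizes inclusion depth directly below the
  source-detector midline; the side-surface optode arrangement of the
  physical switchable phantom is not modelled geometrically.
* SNIRF/HDF5 export is intentionally not implemented; the interchange
  format is CSV + JSON sidecar.
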