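# nirsbench

Performance assessment of time-domain diffuse optics (TD-NIRS) instruments,
fully executable at desk scale: a diffusion-theory forward model, a virtual
TCSPC instrument with virtual phantom kits, a canonical optical-property
retrieval, and the figures of merit of the three consolidated protocol
families — **BIP** (basic instrument performance), **MEDPHOT**
(homogeneous optical properties) and **nEUROPt** (inhomogeneity
detection).

## Who this is for

Diffuse-optics instrument builders and labs that grade instruments with
phantom protocols. Real multi-laboratory exercises measure physical
phantom kits; every test here runs instead against a *virtual* instrument
and *virtual* phantoms with controlled, seedable defects (IRF width and
tail, dark counts, DNL, drift, day-to-day jitter, photon noise), so each
figure of merit can be exercised, unit-tested and power-analyzed without
hardware.

## The models in brief

Time-resolved reflectance of a semi-infinite turbid medium
(extrapolated-boundary dipole, source depth `z0 = 1/musp`, `D = 1/(3
musp)`):

    R(rho, t) = (4 pi D v)^(-3/2) t^(-5/2) exp(-mua v t - rho^2 / (4 D v t))
                x 1/2 [ z0 e^(-z0^2/4Dvt) + (z0 + 2 zb) e^(-(z0+2zb)^2/4Dvt) ]

with `v = c/n` and `zb = 2AD` from the Fresnel mismatch factor A. Slab
transmittance uses the image-source series. A small absorbing inclusion
(equivalent `dmua x V`, default 0.17 cm^-1 x 1 cm^3) enters through the
first-order Born perturbation, evaluated in closed form.

Synthetic histograms are Poisson samples of `(model ⊛ IRF) + dark`,
channel-weighted by a static DNL pattern. Retrieval minimizes the Poisson
deviance of `amplitude x (model ⊛ IRF)` over a configurable fit range
(80% of peak on the rise to 1% on the tail), with the amplitude profiled
out so the estimate is shape-only.

Figures of merit include: IRF FWHM; responsivity
`Ntot/(tmeas kappa_p Pin)` (m^2 sr); DNL `(max-min)/mean`; dark count
rate; deviation-from-median accuracy; deviation-from-linearity and
relative crosstalk coupling `F` (a coupling `F` with a d% cause produces
an `F x d%` effect); stability range and drift; counts needed for a 1%
coefficient of variation; between-session reproducibility; and
time-windowed contrast `(Mi - M0)/M0` and CNR `(Mi - M0)/sigma(M0)` over
a depth scan, reported at the late window (2000-2400 ps) and 20 mm depth.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```python
import numpy as np
import nirsbench as nb
from nirsbench.retrieval import fit_optical_properties

# a mid-range virtual instrument: 300-ps IRF, 1 kcps dark rate
instr = nb.InstrumentModel(irf=nb.IRFModel(fwhm_ps=300.0), dark_rate_cps=1000.0)
irf = nb.make_irf(instr.irf, instr, total_counts=1e6, seed=0)
geo = nb.Geometry(rho_mm=30.0)

# measure virtual kit phantom B3 (mua=0.1, musp=10 cm^-1) for 1 s at 5e5 cps
phantom = nb.OpticalProperties(mua=0.1, musp=10.0)
dtof = nb.synthesize_dtof(phantom, geo, instr, signal_counts=5e5, seed=42)
res = fit_optical_properties(dtof, irf, geo)
print(f"retrieved mua  = {res.props.mua:.4f} cm^-1")
print(f"retrieved musp = {res.props.musp:.3f} cm^-1")

# depth scan of the switchable phantom's absorbing inclusion
scan = nb.synthesize_depth_scan(instr, np.arange(4.0, 31.0, 2.0), n_reps=20, seed=7)
prof = nb.depth_profile(scan)
fom = nb.neuropt_fom(prof, depth_mm=20.0, window="late")
print(f"late-window contrast at 20 mm = {fom.contrast_abs:.3f}")
print(f"late-window CNR at 20 mm      = {fom.cnr_abs:.1f}")
```

Output:

    retrieved mua  = 0.0992 cm^-1
    retrieved musp = 9.847 cm^-1
    late-window contrast at 20 mm = 0.134
    late-window CNR at 20 mm      = 19.3

The retrieved properties sit within the photon-noise uncertainty of the
phantom's true values (~1% at 5e5 counts). The detection indicators say
that with the inclusion 20 mm deep, late-arriving photons still lose
13% of their counts (contrast 0.134), and that this loss is 19 baseline
standard deviations — comfortably detectable; a continuous-wave analysis
of the same scan (`nb.cw_contrast`) sees only ~3% contrast at that depth.

A full virtual multi-instrument exercise, with the population summary
table (count / mean / std / quartiles per FOM):

    nirsbench campaign --n-instruments 3 --seed 1 --out results/

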