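"""Virtual-instrument generator: kit grid, IRF synthesis, DTOF statistics,
protocol series and the responsivity round trip."""
import numpy as np
import pytest

from nirsbench import (
    Geometry,
    IRFModel,
    InclusionSpec,
    InstrumentModel,
    OpticalProperties,
    make_irf,
    medphot_kit,
    synthesize_dark,
    synthesize_depth_scan,
    synthesize_dnl_measurement,
    synthesize_dtof,
    synthesize_dtof_replicates,
    synthesize_noise_series,
    synthesize_responsivity_measurement,
    synthesize_sessions,
    synthesize_stability_series,
)
from nirsbench.bip import dnl_eps, responsivity
from nirsbench.forward import td_reflectance
from nirsbench.instrument import kit_phantom


class TestKit:
    def test_full_grid_has_32_phantoms(self):
        kit = medphot_kit()
        assert len(kit) == 32
        assert len({p.label for p in kit}) == 32

    @pytest.mark.parametrize(
        "label,mua,musp",
        [("B2", 0.05, 10.0), ("B3", 0.1, 10.0), ("A1", 0.0, 5.0), ("D8", 0.35, 20.0)],
    )
    def test_grid_convention(self, label, mua, musp):
        p = kit_phantom(label)
        assert p.nominal.mua == pytest.approx(mua)
        assert p.nominal.musp == pytest.approx(musp)

    def test_grid_steps(self):
        kit = medphot_kit()
        muas = sorted({p.nominal.mua for p in kit})
        musps = sorted({p.nominal.musp for p in kit})
        np.testing.assert_allclose(muas, np.arange(0, 0.351, 0.05), atol=1e-12)
        np.testing.assert_allclose(musps, [5, 10, 15, 20])


class TestMakeIrf:
    def test_gaussian_fwhm_round_trip(self):
        instr = InstrumentModel()
        irf = make_irf(IRFModel(fwhm_ps=200.0), instr, total_counts=1e6)
        from nirsbench.bip import irf_fwhm

        assert irf_fwhm(irf) == pytest.approx(200.0, abs=instr.channel_width_ps)

    def test_area_matches_requested_counts(self):
        instr = InstrumentModel()
        irf = make_irf(IRFModel(fwhm_ps=300.0), instr, total_counts=5e5)
        assert irf.expectation.sum() == pytest.approx(5e5, rel=1e-3)

    def test_exponential_tail_shifts_mean_time(self):
        """First moment of the Gaussian+tail mixture exceeds the pure
        Gaussian's; oracle = analytic mean of the mixture (t0 + f*tau)."""
        instr = InstrumentModel()
        plain = make_irf(IRFModel(fwhm_ps=300.0), instr, total_counts=1e6)
        tailed = make_irf(
            IRFModel(fwhm_ps=300.0, tail_fraction=0.3, tail_tau_ps=500.0),
            instr, total_counts=1e6)

        def mean_time(d):
            return np.sum(d.times_ps * d.expectation) / d.expectation.sum()

        shift = mean_time(tailed) - mean_time(plain)
        assert shift == pytest.approx(0.3 * 500.0, rel=0.05)

    def test_unresolvable_fwhm_rejected(self):
        instr = InstrumentModel(channel_width_ps=50.0)
        with pytest.raises(ValueError, match="resolved"):
            make_irf(IRFModel(fwhm_ps=10.0), instr)

    def test_poisson_sampling_reproducible(self):
        instr = InstrumentModel()
        a = make_irf(IRFModel(), instr, seed=7)
        b = make_irf(IRFModel(), instr, seed=7)
        np.testing.assert_array_equal(a.counts, b.counts)


class TestSynthesizeDtof:
    def test_same_seed_bit_identical(self, b3_props, geometry, ideal_instrument):
        a = synthesize_dtof(b3_props, geometry, ideal_instrument, seed=3)
        b = synthesize_dtof(b3_props, geometry, ideal_instrument, seed=3)
        np.testing.assert_array_equal(a.counts, b.counts)
        c = synthesize_dtof(b3_props, geometry, ideal_instrument, seed=4)
        assert np.any(a.counts != c.counts)

    def test_mean_total_counts_poisson_consistent(self, b3_props, geometry):
        """Replicate mean within 3 standard errors of signal + dark total."""
        instr = InstrumentModel(
            irf=IRFModel(fwhm_ps=200.0), dark_rate_cps=2000.0)
        n, target = 100, 2e4
        reps = synthesize_dtof_replicates(
            b3_props, geometry, instr, n, signal_counts=target, seed=11)
        totals = np.array([r.total_counts for r in reps])
        expected = reps[0].expectation.sum()
        assert expected == pytest.approx(target + 2000.0, rel=0.01)
        se = np.sqrt(expected / n)
        assert abs(totals.mean() - expected) < 3 * se

    def test_delta_irf_expectation_proportional_to_forward_model(
        self, b3_props, geometry, delta_instrument
    ):
        d = synthesize_dtof(b3_props, geometry, delta_instrument,
                            signal_counts=1e6, seed=None)
        t = d.times_ps
        fwd = td_reflectance(geometry.rho_mm, t, b3_props, geometry)
        ok = fwd > fwd.max() * 1e-9
        ratio = d.expectation[ok] / fwd[ok]
        assert np.max(np.abs(ratio / ratio.mean() - 1.0)) < 1e-6

    def test_dnl_pattern_multiplies_expectation(self, b3_props, geometry):
        base = InstrumentModel()
        k = np.arange(base.n_channels)
        pattern = 1.0 + 0.1 * np.sin(2 * np.pi * 5 * k / base.n_channels)
        pattern = pattern / pattern.mean()
        instr = InstrumentModel(dnl_pattern=pattern)
        plain = synthesize_dtof(b3_props, geometry, base, seed=None)
        mod = synthesize_dtof(b3_props, geometry, instr, seed=None)
        np.testing.assert_allclose(
            mod.expectation, plain.expectation * pattern, rtol=1e-12)


class TestProtocolSeries:
    def test_stability_series_length_and_warning(self, b2_props, ideal_instrument):
        minutes, series = synthesize_stability_series(
            b2_props, ideal_instrument, duration_min=60, period_s=300,
            n_reps=2, seed=1)
        assert len(series) == 13 and minutes.size == 13
        assert all(len(reps) == 2 for reps in series)
        with pytest.warns(UserWarning, match="60 min"):
            synthesize_stability_series(
                b2_props, ideal_instrument, duration_min=30, period_s=300,
                n_reps=2, seed=1)

    def test_amplitude_drift_applied_linearly(self, b2_props):
        instr = InstrumentModel(drift_amp_per_min=0.01)
        minutes, series = synthesize_stability_series(
            b2_props, instr, duration_min=60, period_s=600, n_reps=1, seed=1)
        totals = np.array([reps[0].expectation.sum() for reps in series])
        ratio = totals / totals[0]
        np.testing.assert_allclose(ratio, 1.0 + 0.01 * minutes, rtol=1e-9)

    def test_t0_drift_propagates_into_retrieved_properties(self, b2_props, geometry):
        """A 1 ps/min timing drift produces a clear monotone trend in the
        retrieved absorption when t0 is calibrated once from the IRF."""
        from nirsbench import make_irf
        from nirsbench.retrieval import FitOptions, fit_optical_properties

        drifting = InstrumentModel(drift_t0_ps_per_min=1.0)
        irf = make_irf(drifting.irf, drifting, 1e6)
        minutes, series = synthesize_stability_series(
            b2_props, drifting, duration_min=60, period_s=900, n_reps=4,
            signal_counts=1e6, seed=29)
        opts = FitOptions(fit_t0=False)
        mua = [np.mean([fit_optical_properties(d, irf, geometry, opts).props.mua
                        for d in reps]) for reps in series]
        slope = np.polyfit(minutes, mua, 1)[0]
        resid = np.std(np.asarray(mua) - np.polyval(np.polyfit(minutes, mua, 1), minutes))
        assert abs(slope) * (minutes.max() - minutes.min()) > 5 * resid

    def test_session_jitter_inflates_reproducibility(self, b2_props, geometry):
        """Day-to-day jitter raises the between-session CV of retrieved
        properties relative to the jitter-free instrument."""
        from nirsbench import IRFModel, make_irf
        from nirsbench.medphot import reproducibility_fom
        from nirsbench.retrieval import FitOptions, fit_optical_properties

        opts = FitOptions(fit_t0=False)
        cvs = {}
        for jitter in (0.0, 0.05):
            instr = InstrumentModel(irf=IRFModel(fwhm_ps=300.0), session_jitter=jitter)
            irf = make_irf(instr.irf, instr, 1e6)
            sessions = synthesize_sessions(
                b2_props, instr, n_sessions=3, n_reps=5,
                geometry=geometry, signal_counts=1e6, seed=37)
            means = [np.mean([fit_optical_properties(d, irf, geometry, opts).props.mua
                              for d in sess]) for sess in sessions]
            cvs[jitter] = reproducibility_fom(means)
        assert cvs[0.05] > cvs[0.0]

    def test_noise_series_totals_ordered(self, b2_props, ideal_instrument):
        levels = [1e4, 1e5, 1e6]
        out = synthesize_noise_series(
            b2_props, ideal_instrument, levels, n_reps=5, seed=2)
        means = [np.mean([d.total_counts for d in out[lv]]) for lv in levels]
        assert means[0] < means[1] < means[2]
        # distinct sub-seeds: replicates differ
        assert np.any(out[1e5][0].counts != out[1e5][1].counts)

    def test_poisson_variance_mean_unity(self, b2_props, ideal_instrument):
        """Across replicates the per-channel variance/mean ratio ~ 1."""
        reps = synthesize_dtof_replicates(
            b2_props, Geometry(), ideal_instrument, 60,
            signal_counts=1e5, seed=21)
        counts = np.array([r.counts for r in reps], dtype=float)
        lam = reps[0].expectation
        busy = lam > 50
        ratio = counts.var(axis=0, ddof=1)[busy] / lam[busy]
        assert ratio.mean() == pytest.approx(1.0, abs=0.1)

    def test_sessions_count_and_jitter_effect(self, b2_props):
        still = InstrumentModel.ideal()
        sessions = synthesize_sessions(b2_props, still, n_sessions=3,
                                       n_reps=2, seed=5)
        assert len(sessions) == 3 and all(len(s) == 2 for s in sessions)
        jittery = InstrumentModel(
            irf=IRFModel(fwhm_ps=300.0), session_jitter=0.05)
        sessions_j = synthesize_sessions(b2_props, jittery, n_sessions=3,
                                         n_reps=2, seed=5)
        t0s = {s[0].meta["session_t0_ps"] for s in sessions_j}
        assert len(t0s) == 3 and any(abs(x) > 0.1 for x in t0s)


class TestDnlAndDark:
    def test_flat_pattern_near_poisson_floor(self):
        instr = InstrumentModel()
        hist = synthesize_dnl_measurement(instr, counts_per_channel=1e5, seed=3)
        # pure Poisson peak-to-peak over mean: ~2 * (max |z|) / sqrt(N)
        assert dnl_eps(hist) <= 5 * 2 * np.sqrt(1.0 / 1e5) * 4

    def test_expectation_proportional_to_pattern(self):
        base = InstrumentModel()
        k = np.arange(base.n_channels)
        pattern = 1.0 + 0.1 * np.sin(2 * np.pi * 3 * k / base.n_channels)
        pattern /= pattern.mean()
        instr = InstrumentModel(dnl_pattern=pattern)
        hist = synthesize_dnl_measurement(instr, 1e5, seed=None)
        np.testing.assert_allclose(hist.expectation, 1e5 * pattern, rtol=1e-12)

    def test_dark_totals_and_zero_rate(self):
        instr = InstrumentModel(dark_rate_cps=1000.0)
        dark = synthesize_dark(instr, tmeas_s=10.0, seed=4)
        assert dark.expectation.sum() == pytest.approx(1e4)
        assert np.ptp(dark.expectation) == 0.0  # uniform in expectation
        silent = synthesize_dark(InstrumentModel(), tmeas_s=10.0, seed=4)
        assert silent.total_counts == 0


class TestDepthScan:
    def test_null_inclusion_contrast_consistent_with_zero(self, ideal_instrument):
        scan = synthesize_depth_scan(
            ideal_instrument, [10.0, 20.0],
            inclusion=InclusionSpec(depth_mm=10.0, delta_mua=0.0),
            n_reps=10, signal_counts=1e5, seed=6)
        base_mean = np.mean([b.total_counts for b in scan.baseline])
        for reps in scan.dtofs:
            m = np.mean([r.total_counts for r in reps])
            # ~3 sigma of the mean of 10 Poisson totals
            assert abs(m - base_mean) < 3 * np.sqrt(1e5 / 10) * np.sqrt(2)

    def test_perturbed_totals_below_baseline_in_expectation(self, ideal_instrument):
        scan = synthesize_depth_scan(
            ideal_instrument, [8.0, 15.0, 25.0], n_reps=2,
            signal_counts=1e5, seed=7)
        base_exp = scan.baseline[0].expectation.sum()
        for reps in scan.dtofs:
            assert reps[0].expectation.sum() < base_exp


class TestResponsivityRoundTrip:
    def test_recovers_true_value_within_poisson_error(self):
        instr = InstrumentModel()
        true = 1.2e-8
        inp = synthesize_responsivity_measurement(
            instr, true_responsivity=true, seed=8)
        est = responsivity(inp)
        rel_err = 1.0 / np.sqrt(inp.Ntot)  # Poisson relative error on Ntot
        assert est == pytest.approx(true, rel=5 * rel_err)

    def test_ntot_scales_with_tmeas(self):
        instr = InstrumentModel()
        a = synthesize_responsivity_measurement(instr, tmeas_s=1.0, seed=None)
        b = synthesize_responsivity_measurement(instr, tmeas_s=10.0, seed=None)
        assert b.Ntot == pytest.approx(10 * a.Ntot)

    def test_zero_power_rejected(self):
        with pytest.raises(ValueError):
            synthesize_responsivity_measurement(InstrumentModel(), Pin_W=0.0)
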