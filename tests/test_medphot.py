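"""MEDPHOT indicator arithmetic: accuracy, linearity, crosstalk, stability,
CV, noise interpolation and reproducibility."""
import numpy as np
import pandas as pd
import pytest

from nirsbench.medphot import (
    KitMeasurement,
    accuracy_deviation,
    coupling_effect_pct,
    crosstalk_fom,
    cv,
    drift_projection,
    linearity_fom,
    noise_fom,
    reproducibility_fom,
    stability_fom,
)


def make_kit(mua_fn, mus_fn) -> KitMeasurement:
    """Synthetic kit table: retrieved = fn(nominal_mua, nominal_mus)."""
    rows = []
    letters = {"A": 5.0, "B": 10.0, "C": 15.0, "D": 20.0}
    for letter, musp in letters.items():
        for digit in range(1, 9):
            mua = 0.05 * (digit - 1)
            rows.append({
                "label": f"{letter}{digit}",
                "nominal_mua": mua, "nominal_mus": musp,
                "mua": mua_fn(mua, musp), "mus": mus_fn(mua, musp),
            })
    return KitMeasurement(records=pd.DataFrame(rows))


class TestAccuracy:
    def test_identical_instruments_zero_deviation(self):
        res = accuracy_deviation([0.1, 0.1, 0.1])
        assert np.all(res.deviations_pct == 0) and res.median_pct == 0

    def test_worked_example(self):
        res = accuracy_deviation([0.09, 0.10, 0.11])
        np.testing.assert_allclose(sorted(res.deviations_pct), [0.0, 10.0, 10.0])
        assert res.median_pct == pytest.approx(10.0)

    def test_scale_invariance(self):
        a = accuracy_deviation([0.09, 0.10, 0.12])
        b = accuracy_deviation([0.9, 1.0, 1.2])
        np.testing.assert_allclose(a.deviations_pct, b.deviations_pct)

    def test_too_few_instruments_rejected(self):
        with pytest.raises(ValueError):
            accuracy_deviation([0.1, 0.2])


class TestLinearity:
    def test_exactly_linear_kit_is_zero(self):
        kit = make_kit(lambda a, s: 0.01 + 0.95 * a, lambda a, s: 1.1 * s - 0.2)
        lin_mua, lin_mus = linearity_fom(kit)
        assert lin_mua == pytest.approx(0.0, abs=1e-10)
        assert lin_mus == pytest.approx(0.0, abs=1e-10)

    def test_against_brute_force_regression(self):
        """Median |y - yhat|/yhat over the series, against an explicit
        regression computed point by point."""
        rng = np.random.default_rng(42)
        noise = {}

        def mua_fn(a, s):
            noise[(a, s)] = rng.normal(0, 0.002)
            return a + noise[(a, s)]

        kit = make_kit(mua_fn, lambda a, s: s)
        devs = []
        df = kit.records
        for letter in "ABCD":
            sub = df[df["label"].str.startswith(letter)]
            x, y = sub["nominal_mua"].to_numpy(), sub["mua"].to_numpy()
            coef = np.polyfit(x, y, 1)
            yhat = np.polyval(coef, x)
            devs.extend(np.abs(y - yhat) / np.abs(yhat) * 100)
        expected = np.median(devs)
        assert linearity_fom(kit)[0] == pytest.approx(expected, rel=1e-9)

    def test_series_order_irrelevant(self):
        kit = make_kit(lambda a, s: a + 0.001 * (a * 7 % 0.01), lambda a, s: s)
        shuffled = KitMeasurement(
            records=kit.records.sample(frac=1.0, random_state=1).reset_index(drop=True))
        assert linearity_fom(kit) == pytest.approx(linearity_fom(shuffled))


class TestCrosstalk:
    def test_uncoupled_kit_zero_coupling(self):
        kit = make_kit(lambda a, s: a, lambda a, s: s)
        xt = crosstalk_fom(kit)
        assert xt.F_mus_to_mua == pytest.approx(0.0, abs=1e-12)
        assert xt.F_mua_to_mus == pytest.approx(0.0, abs=1e-12)

    def test_injected_coupling_recovered(self):
        """Retrieved mua = true + 0.001 (nominal musp - 10) gives
        S = 0.001 and F_mus_to_mua = 0.001 * 10 / 0.1 = 0.1."""
        kit = make_kit(lambda a, s: a + 0.001 * (s - 10.0), lambda a, s: s)
        xt = crosstalk_fom(kit)
        assert xt.S_mua_given_mus == pytest.approx(0.001, rel=1e-9)
        assert xt.F_mus_to_mua == pytest.approx(0.1, rel=1e-9)

    def test_worked_coupling_effect(self):
        """F = 0.13 and a 10% cause increment give a 1.3% effect."""
        assert coupling_effect_pct(0.13, 10.0) == pytest.approx(1.3)


class TestStability:
    def test_constant_series(self):
        minutes = np.linspace(0, 90, 16)
        st = stability_fom(minutes, np.full(16, 0.1))
        assert st.range_pct == 0.0
        assert st.drift_pct_per_min == pytest.approx(0.0, abs=1e-10)

    def test_linear_ramp_arithmetic(self):
        """0.100 -> 0.102 cm^-1 over 100 min: range 1.98%, drift 0.0198 %/min
        (mean = 0.101)."""
        minutes = np.linspace(0, 100, 21)
        values = np.linspace(0.100, 0.102, 21)
        st = stability_fom(minutes, values)
        assert st.range_pct == pytest.approx(100 * 0.002 / 0.101, rel=1e-9)
        assert st.drift_pct_per_min == pytest.approx(100 * 2e-5 / 0.101, rel=1e-9)

    def test_time_reversal_preserves_magnitudes(self):
        minutes = np.linspace(0, 80, 12)
        values = 0.1 + 1e-5 * minutes + 1e-4 * np.sin(minutes)
        fwd = stability_fom(minutes, values)
        rev = stability_fom(minutes, values[::-1])
        assert rev.range_pct == pytest.approx(fwd.range_pct)
        assert rev.drift_pct_per_min == pytest.approx(fwd.drift_pct_per_min, rel=1e-6)

    def test_short_series_warns(self):
        with pytest.warns(UserWarning):
            stability_fom([0, 10, 20, 30, 40, 50, 55, 56, 57, 58],
                          np.linspace(0.1, 0.101, 10))

    def test_drift_projection(self):
        assert drift_projection(0.03, 100) == pytest.approx(3.0)
        assert drift_projection(0.5, 0) == 0.0
        # additivity over split intervals
        assert drift_projection(0.02, 30) + drift_projection(0.02, 70) == \
            pytest.approx(drift_projection(0.02, 100))


class TestCv:
    def test_constant_zero(self):
        assert cv([5.0, 5.0, 5.0]) == 0.0

    def test_sample_sd_convention(self):
        assert cv([9, 10, 11]) == pytest.approx(10.0)  # sd(n-1)=1, mean=10

    def test_scale_invariance(self):
        assert cv([9, 10, 11]) == pytest.approx(cv([90, 100, 110]))


class TestNoiseFom:
    @staticmethod
    def _estimates_with_cv(target_cv_pct, n=400, mean=0.1, seed=0):
        rng = np.random.default_rng(seed)
        draws = rng.normal(mean, mean * target_cv_pct / 100, size=n)
        # rescale so the sample CV is exactly the target
        draws = mean + (draws - draws.mean()) * \
            (mean * target_cv_pct / 100) / draws.std(ddof=1)
        return draws + (mean - draws.mean())

    def test_closed_form_inversion(self):
        """CV = 2% * sqrt(1e5/N) sampled at 1e4, 1e5, 1e6 -> N* = 4e5."""
        levels = [1e4, 1e5, 1e6]
        ests = [self._estimates_with_cv(2.0 * np.sqrt(1e5 / N), seed=i)
                for i, N in enumerate(levels)]
        assert noise_fom(levels, ests) == pytest.approx(4e5, rel=1e-6)

    def test_level_reordering_invariant(self):
        levels = [1e6, 1e4, 1e5]
        ests = [self._estimates_with_cv(2.0 * np.sqrt(1e5 / N), seed=int(N))
                for N in levels]
        reordered = noise_fom(levels[::-1], ests[::-1])
        assert noise_fom(levels, ests) == pytest.approx(reordered, rel=1e-9)

    def test_increasing_cv_rejected(self):
        levels = [1e4, 1e5, 1e6]
        ests = [self._estimates_with_cv(c, seed=int(c * 10))
                for c in (1.0, 2.0, 4.0)]
        with pytest.raises(ValueError, match="degenerate"):
            noise_fom(levels, ests)


class TestNoiseFomEndToEnd:
    def test_within_factor_2_of_analytic_extrapolation(
        self, b2_props, geometry, ideal_instrument, ideal_irf
    ):
        """On pure-Poisson synthetic data the interpolated counts-for-1%-CV
        agree within a factor 2 with the value implied by the observed CV at
        each simulated level under 1/sqrt(N) scaling."""
        from nirsbench import synthesize_noise_series
        from nirsbench.retrieval import FitOptions, fit_optical_properties

        levels = [1e5, 3e5, 1e6]
        series = synthesize_noise_series(
            b2_props, ideal_instrument, levels, n_reps=15,
            geometry=geometry, seed=31)
        opts = FitOptions(fit_t0=False)
        ests = []
        for level in levels:
            ests.append([
                fit_optical_properties(d, ideal_irf, geometry, opts).props.mua
                for d in series[level]])
        n_star = noise_fom(levels, ests)
        for level, est in zip(levels, ests):
            implied = level * cv(est) ** 2  # N at CV=1% assuming CV ~ N^-1/2
            assert 0.5 < n_star / implied < 2.0


class TestReproducibility:
    def test_identical_sessions_zero(self):
        assert reproducibility_fom([0.1, 0.1, 0.1]) == pytest.approx(0.0, abs=1e-10)

    def test_worked_example(self):
        """Sessions {0.10, 0.10, 0.11}: mean 0.10333, sd 0.005774 -> 5.59%."""
        assert reproducibility_fom([0.10, 0.10, 0.11]) == pytest.approx(5.587, abs=0.01)

    def test_permutation_invariance(self):
        assert reproducibility_fom([0.10, 0.11, 0.10]) == \
            pytest.approx(reproducibility_fom([0.11, 0.10, 0.10]))
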