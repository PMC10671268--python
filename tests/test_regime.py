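"""Cross-series regressions: order, Hill, non-aggregated decay, kII."""

import numpy as np
import pytest

from aggkinetics import (
    NonAggTrace,
    classify_regime,
    eval_hill,
    eval_nonagg,
    fit_dose_response,
    fit_first_order,
    fit_nonagg_curve,
    fit_order,
    fit_second_order,
    intensity_vs_aggregated,
    second_order_transform,
    synth_second_order_gamma,
)
from aggkinetics.datatypes import KineticTrace, OrderFit
from aggkinetics.regime import HillCurve, NonAggDecay, PowerLaw, SecondOrderRate

CONCS = np.linspace(0.1, 0.6, 6)


class TestOrderFit:
    def test_exact_power_law(self):
        fit = fit_order(CONCS, 3.0 * CONCS**2)
        assert fit.b == pytest.approx(2.0, abs=1e-8)
        assert fit.const == pytest.approx(3.0, rel=1e-8)
        assert fit.n_c == 2

    def test_loglog_ols_oracle_on_clean_data(self):
        y = 0.7 * CONCS**1.37
        slope = np.polyfit(np.log(CONCS), np.log(y), 1)[0]
        assert fit_order(CONCS, y).b == pytest.approx(slope, abs=1e-8)

    def test_monte_carlo_recovery_b_1p11(self):
        rng = np.random.default_rng(5)
        bs = []
        for _ in range(100):
            y = 2.0 * CONCS**1.11 * (1 + 0.05 * rng.standard_normal(6))
            bs.append(PowerLaw().fit(CONCS, y).b_)
        assert np.mean(bs) == pytest.approx(1.11, abs=0.1)

    @pytest.mark.parametrize("b_true", [0.5, 1.0, 2.0, 3.5, 5.0])
    def test_recovery_sweep_small_bias(self, b_true):
        rng = np.random.default_rng(int(b_true * 10))
        bs = []
        for _ in range(60):
            y = CONCS**b_true * (1 + 0.05 * rng.standard_normal(6))
            bs.append(PowerLaw().fit(CONCS, y).b_)
        assert abs(np.mean(bs) - b_true) < 0.15

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            fit_order(CONCS, np.array([1, 2, 3, 4, 5, 0.0]))
        with pytest.raises(ValueError):
            fit_order(CONCS[:2], np.ones(2))


class TestHillFit:
    L = np.array([0.0, 10.0, 25.0, 50.0, 75.0, 100.0])

    def test_noise_free_exact_recovery(self):
        y = 5.0 * eval_hill(self.L, 52.0, 1.8)
        fit = fit_dose_response(self.L, y)
        assert fit.L_half == pytest.approx(52.0, rel=1e-6)
        assert fit.h == pytest.approx(1.8, rel=1e-6)
        assert fit.baseline == pytest.approx(5.0)

    def test_scale_invariance(self):
        y = eval_hill(self.L, 30.0, 1.2)
        f1 = fit_dose_response(self.L, y)
        f2 = fit_dose_response(self.L, 137.0 * y)
        assert f2.L_half == pytest.approx(f1.L_half, rel=1e-9)
        assert f2.h == pytest.approx(f1.h, rel=1e-9)

    def test_half_ratio_at_semi_saturation(self):
        for h in (0.7, 1.1, 1.8, 3.0):
            fit = HillCurve(baseline=1.0).fit(self.L, eval_hill(self.L, 52.0, h))
            assert fit.predict([fit.L_half_])[0] == pytest.approx(0.5)

    def test_monte_carlo_L_half_within_10pct(self):
        rng = np.random.default_rng(9)
        Lh = []
        for _ in range(100):
            y = eval_hill(self.L, 52.0, 1.8) * (1 + 0.03 * rng.standard_normal(6))
            Lh.append(HillCurve(baseline=1.0).fit(self.L, y).L_half_)
        assert np.mean(Lh) == pytest.approx(52.0, rel=0.10)

    def test_no_suppression_warns(self):
        with pytest.warns(UserWarning):
            HillCurve(baseline=1.0).fit(self.L, np.full(6, 1.02))


class TestNonAggFit:
    def test_noise_free_exact_recovery(self):
        t = np.linspace(0, 80, 41)
        trace = NonAggTrace(t=t, gamma=eval_nonagg(t, 2.0, 10.0, 2.0))
        fit = fit_nonagg_curve(trace)
        assert fit.t_star == pytest.approx(2.0, abs=1e-4)
        assert fit.t_half == pytest.approx(10.0, rel=1e-5)
        assert fit.m == pytest.approx(2.0, rel=1e-5)

    def test_half_decay_holds_on_fitted_curve(self):
        t = np.linspace(0, 120, 61)
        rng = np.random.default_rng(3)
        gamma = eval_nonagg(t, 5.0, 20.0, 2.5)
        gamma = np.clip(gamma * (1 + 0.01 * rng.standard_normal(len(t))), 1e-6, 1.0)
        est = NonAggDecay().fit(t, gamma)
        assert est.predict([est.t_star_ + est.t_half_])[0] == pytest.approx(0.5)

    def test_exponential_limit_flagged_at_lower_bound(self):
        t = np.linspace(0, 60, 31)
        trace = NonAggTrace(t=t, gamma=np.exp(-t / 15.0))
        fit = fit_nonagg_curve(trace)
        assert fit.at_lower_bound
        assert fit.m < 1.05

    def test_rising_gamma_rejected(self):
        t = np.linspace(0, 60, 20)
        with pytest.raises(ValueError):
            NonAggDecay().fit(t, np.linspace(0.5, 1.0, 20))


class TestSecondOrderFit:
    def test_exact_decay_recovers_slope(self):
        trace = synth_second_order_gamma(np.linspace(0, 60, 31), 2.67e-6, 69.0)
        fit = fit_second_order(trace, 2.67e-6)
        assert fit.k_II == pytest.approx(69.0, rel=1e-9)
        assert fit.intercept == pytest.approx(0.0, abs=1e-3)
        assert fit.r_squared > 0.999999

    def test_monte_carlo_slope_within_5pct(self):
        ks = []
        for seed in range(100):
            trace = synth_second_order_gamma(np.linspace(0, 60, 31), 2.67e-6,
                                             69.0, noise_sd_frac=0.02, seed=seed)
            ks.append(fit_second_order(trace, 2.67e-6).k_II)
        assert np.mean(ks) == pytest.approx(69.0, rel=0.05)

    def test_first_order_data_fits_worse_than_second_order(self):
        t = np.linspace(0, 60, 31)
        c0, k = 2.67e-6, 69.0
        second = synth_second_order_gamma(t, c0, k)
        # first-order decay with the same half-life
        t_half_s = 1.0 / (c0 * k) / 60.0
        first = NonAggTrace(t=t, gamma=np.exp(-np.log(2) * t / t_half_s))
        r2_second = fit_second_order(second, c0).r_squared
        r2_first = fit_second_order(first, c0).r_squared
        assert r2_second > r2_first

    def test_subsampling_invariance(self):
        trace = synth_second_order_gamma(np.linspace(0, 60, 61), 2.67e-6, 69.0,
                                         noise_sd_frac=0.02, seed=12)
        full = fit_second_order(trace, 2.67e-6).k_II
        half = SecondOrderRate(c0=2.67e-6, time_unit="min").fit(
            trace.t[::2], trace.gamma[::2]).k_II_
        assert half == pytest.approx(full, rel=0.10)


class TestFirstOrderFit:
    def test_exact_exponential(self):
        t = np.arange(0, 62, 2.0)
        fit = fit_first_order(t, np.exp(-0.060 * t))
        assert fit.k == pytest.approx(0.060, rel=1e-9)


class TestIntensityVsAggregated:
    def _traces(self, power):
        t_s = np.linspace(0, 3600, 121)
        gamma_agg = np.clip(t_s / 3600.0, 0, 1) * 0.9
        I = 100.0 + 5000.0 * gamma_agg**power
        trace = KineticTrace(t=t_s, I=I)
        nonagg = NonAggTrace(t=t_s / 60.0, gamma=1 - gamma_agg)
        return trace, nonagg

    def test_linear_relation_recovered(self):
        trace, nonagg = self._traces(power=1)
        diag = intensity_vs_aggregated(trace, nonagg, power=1)
        assert diag.slope == pytest.approx(5000.0, rel=0.01)
        assert diag.quad_p > 0.5  # no curvature beyond the line

    def test_power_selection_matches_generator(self):
        for power in (1, 2):
            trace, nonagg = self._traces(power=power)
            r2 = {p: intensity_vs_aggregated(trace, nonagg, power=p).r_squared
                  for p in (1, 2)}
            assert r2[power] > r2[3 - power]

    def test_too_few_points_rejected(self):
        trace, _ = self._traces(power=1)
        short = NonAggTrace(t=np.array([0.0, 1.0, 2.0]),
                            gamma=np.array([1.0, 0.9, 0.8]))
        with pytest.raises(ValueError):
            intensity_vs_aggregated(trace, short)


class TestClassifyRegime:
    def make(self, b):
        return OrderFit(b=b, const=1.0, b_stderr=0.05, n_c=round(b))

    def test_first_order_growth_is_denaturation_limited(self):
        call = classify_regime(self.make(1.11), self.make(2.1))
        assert call.limiting_stage == "denaturation"
        assert call.n_c_growth == 1
        assert call.n_c_nucleation == 2

    def test_second_order_growth_is_growth_limited(self):
        call = classify_regime(self.make(2.2), self.make(4.3))
        assert call.limiting_stage == "aggregate_growth"
        assert call.n_c_growth == 2
        assert call.n_c_nucleation == 4

    def test_midpoint_is_indeterminate(self):
        call = classify_regime(self.make(1.5), self.make(2.0))
        assert call.limiting_stage == "indeterminate"


class TestSecondOrderTransformComposition:
    def test_transform_of_exact_decay_is_linear_with_slope_k(self):
        c0, k = 1.5e-6, 42.0
        t = np.linspace(0, 1000, 200)
        y = second_order_transform(1 / (1 + c0 * k * t), c0)
        resid = y - k * t
        assert np.max(np.abs(resid)) < 1e-6 * np.max(y)
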