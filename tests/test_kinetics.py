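"""Hill dispersion model: evaluation, rate laws, ODE consistency, fitting,
and the regression-statistics panel."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deswax.kinetics import (
    FitStats,
    HillParams,
    HillRegressor,
    KineticSeries,
    LinearMap,
    fit_hill,
    fit_stats,
    hill_eval,
    hill_rate,
    integrate_ode,
    linear_correlation,
    noyes_whitney_rate,
    prediction_interval,
    relative_error,
)

GRID = np.array([0.0, 30, 60, 120, 240, 360, 480, 720])


class TestHillEval:
    def test_zero_and_half_saturation(self):
        p = HillParams(a=5.0, b=80.0)
        assert hill_eval(p, 0.0) == 0.0
        assert hill_eval(p, 80.0) == pytest.approx(2.5)

    def test_endpoint_value(self):
        assert hill_eval(HillParams(5.0, 80.0), 720.0) == pytest.approx(4.5)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            hill_eval(HillParams(1, 1), -1.0)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        a=st.floats(min_value=0.1, max_value=10),
        b=st.floats(min_value=1, max_value=500),
        t=st.floats(min_value=0, max_value=1e4),
    )
    def test_c1_equals_michaelis_menten(self, a, b, t):
        assert hill_eval(HillParams(a, b, 1.0), t) == pytest.approx(
            a * t / (b + t), rel=1e-12, abs=1e-300
        )

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        a=st.floats(min_value=0.1, max_value=10),
        b=st.floats(min_value=1, max_value=500),
        c=st.floats(min_value=0.5, max_value=4),
    )
    def test_half_saturation_at_b_for_all_shapes(self, a, b, c):
        p = HillParams(a, b, c)
        assert hill_eval(p, b) == pytest.approx(a / 2, rel=1e-12)

    def test_monotone_and_bounded(self):
        p = HillParams(3.0, 50.0, 2.0)
        f = hill_eval(p, np.linspace(0, 5000, 400))
        assert np.all(np.diff(f) > 0)
        assert f[-1] < p.a


class TestRates:
    def test_initial_and_half_rate_quadratic_law(self):
        p = HillParams(a=5.0, b=80.0)
        assert hill_rate(p, 0.0) == pytest.approx(p.a / p.b)
        assert hill_rate(p, p.a / 2) == pytest.approx(p.a / (4 * p.b))

    def test_saturation_exceeded_rejected(self):
        p = HillParams(5.0, 80.0)
        with pytest.raises(ValueError):
            hill_rate(p, 5.0)

    def test_general_shape_reduces_to_quadratic_law_at_c1(self):
        a, b = 4.0, 120.0
        f = np.linspace(0.01, a * 0.999, 200)
        exact = (a / b) * (1 - f / a) ** 2
        # force the general-c branch with c = 1 + 0 ulp equivalent
        general = hill_rate(HillParams(a, b, 1.0 + 1e-15), f)
        assert general == pytest.approx(exact, rel=1e-9)

    def test_general_rate_matches_numerical_derivative(self):
        p = HillParams(a=5.0, b=80.0, c=2.0)
        t = p.b  # where f = a/2
        eps = 1e-5
        numeric = (hill_eval(p, t + eps) - hill_eval(p, t - eps)) / (2 * eps)
        assert hill_rate(p, hill_eval(p, t)) == pytest.approx(numeric, rel=1e-8)

    def test_noyes_whitney_endpoints_and_ratio(self):
        a, b = 5.0, 80.0
        K = a / b
        assert noyes_whitney_rate(K, a, a) == 0.0
        assert noyes_whitney_rate(K, a, 0.0) == K
        f = np.linspace(0, a * 0.99, 50)
        p = HillParams(a, b, 1.0)
        ratio = hill_rate(p, f) / noyes_whitney_rate(K, a, f)
        assert ratio == pytest.approx(1 - f / a, rel=1e-12)


class TestOdeConsistency:
    @pytest.mark.parametrize("a,b,c", [(5.0, 80.0, 1.0), (0.5, 10.0, 0.5),
                                       (2.0, 200.0, 2.0), (10.0, 500.0, 4.0)])
    def test_ode_matches_closed_form(self, a, b, c):
        p = HillParams(a, b, c)
        grid = np.linspace(0, 720, 25)
        series = integrate_ode(p, grid)
        assert np.max(np.abs(series.values - hill_eval(p, grid))) < 1e-6 * a

    def test_fixed_point_at_saturation(self):
        p = HillParams(5.0, 80.0)
        assert hill_rate(p, 5.0 - 1e-12) == pytest.approx(0.0, abs=1e-20)

    def test_large_shape_approaches_logistic_midpoint_slope(self):
        # as c grows, df/dt at f = a/2 tends to the logistic value (a/k)/4
        a, b, c = 2.0, 100.0, 60.0
        p = HillParams(a, b, c)
        rate_mid = hill_rate(p, a / 2)
        logistic_mid = (a / p.k) * 0.25
        assert rate_mid == pytest.approx(logistic_mid, rel=0.05)

    def test_grid_must_start_at_zero(self):
        with pytest.raises(ValueError):
            integrate_ode(HillParams(1, 1), np.array([1.0, 2.0]))


class TestFitting:
    def test_exact_recovery_on_noiseless_data(self):
        truth = HillParams(5.0, 80.0)
        series = KineticSeries(GRID, hill_eval(truth, GRID))
        params, stats = fit_hill(series)
        assert params.a == pytest.approx(5.0, rel=1e-6)
        assert params.b == pytest.approx(80.0, rel=1e-6)
        assert stats.R2 == pytest.approx(1.0)
        assert stats.SE == pytest.approx(0.0, abs=1e-9)

    def test_free_shape_near_one_on_c1_data(self):
        rng = np.random.default_rng(11)
        y = np.clip(hill_eval(HillParams(5.0, 80.0), GRID) + rng.normal(0, 0.05, GRID.size), 0, None)
        params, _ = fit_hill(KineticSeries(GRID, y), fix_c=False)
        assert 0.8 < params.c < 1.2

    def test_noisy_recovery_within_ten_percent(self):
        rng = np.random.default_rng(4)
        y = np.clip(hill_eval(HillParams(5.0, 80.0), GRID) + rng.normal(0, 0.1, GRID.size), 0, None)
        params, _ = fit_hill(KineticSeries(GRID, y))
        assert abs(params.a - 5.0) / 5.0 < 0.10

    def test_estimator_api_and_determinism(self):
        rng = np.random.default_rng(2)
        y = np.clip(hill_eval(HillParams(2.0, 130.0), GRID) + rng.normal(0, 0.05, GRID.size), 0, None)
        r1 = HillRegressor().fit(GRID, y)
        r2 = HillRegressor().fit(GRID, y)
        assert r1.get_params() == {"fix_c": True}
        assert (r1.a_, r1.b_) == (r2.a_, r2.b_)
        assert r1.predict([0.0, 130.0]).shape == (2,)
        assert r1.cov_.shape == (2, 2)
        assert r1.params_.k == r1.params_.b  # c = 1

    def test_rate_constant_relation(self):
        p = HillParams(5.0, 90.0, 3.0)
        assert p.k == pytest.approx(30.0)


class TestStatsPanel:
    def test_information_criterion_identities_small_sample(self):
        # n = 8, k = 2: AICc - AIC = 2k(k+1)/(n-k-1) = 2.4,
        # BIC - AIC = k ln n - 2k = 2 ln 8 - 4
        rng = np.random.default_rng(1)
        obs = hill_eval(HillParams(5, 80), GRID) + rng.normal(0, 0.1, 8)
        pred = hill_eval(HillParams(5, 80), GRID)
        st_ = fit_stats(obs, pred, k_params=2)
        assert st_.n == 8 and st_.DoF == 6
        assert st_.AICc - st_.AIC == pytest.approx(2.4)
        assert st_.BIC - st_.AIC == pytest.approx(2 * math.log(8) - 4)

    def test_perfect_fit_limits(self):
        obs = hill_eval(HillParams(5, 80), GRID)
        st_ = fit_stats(obs, obs, k_params=2)
        assert st_.R2 == 1.0 and st_.SE == 0.0
        assert st_.aR2 <= st_.R2

    def test_adjusted_r2_below_r2(self):
        rng = np.random.default_rng(8)
        obs = hill_eval(HillParams(5, 80), GRID) + rng.normal(0, 0.3, 8)
        st_ = fit_stats(obs, hill_eval(HillParams(5, 80), GRID), k_params=2)
        assert st_.aR2 < st_.R2 < 1.0
        assert 0.0 <= st_.p_value <= 1.0

    def test_degenerate_data_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_stats(np.ones(8), np.ones(8), k_params=2)

    @pytest.mark.parametrize("se, expected", [(27.577, 55.154), (0.0, 0.0), (0.19, 0.38)])
    def test_prediction_interval(self, se, expected):
        assert prediction_interval(se) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "se, value, expected",
        [(0.19, 4.5, 8.44), (0.0, 3.0, 0.0), (0.19, 3.04, 12.5)],
    )
    def test_relative_error(self, se, value, expected):
        assert relative_error(se, value) == pytest.approx(expected, abs=0.05)

    def test_relative_error_rejects_nonpositive_value(self):
        with pytest.raises(ValueError):
            relative_error(0.19, 0.0)


class TestLinearCorrelation:
    def test_noiseless_line_recovered(self):
        mass = KineticSeries(GRID[1:], np.linspace(0.8, 4.5, 7), kind="mass")
        turb_vals = 280.26 * mass.values - 209.14
        turb = KineticSeries(GRID[1:], turb_vals, kind="turbidity")
        lm = linear_correlation(turb, mass)
        assert lm.slope == pytest.approx(280.26)
        assert lm.intercept == pytest.approx(-209.14)
        assert lm.R2 == pytest.approx(1.0)

    def test_constant_mass_rejected(self):
        t = GRID[:5]
        mass = KineticSeries(t, np.full(5, 2.0), kind="mass")
        turb = KineticSeries(t, np.arange(5.0), kind="turbidity")
        with pytest.raises(ValueError, match="degenerate"):
            linear_correlation(turb, mass)

    def test_mismatched_grids_rejected(self):
        mass = KineticSeries(GRID[:5], np.arange(5.0), kind="mass")
        turb = KineticSeries(GRID[1:6], np.arange(5.0), kind="turbidity")
        with pytest.raises(ValueError, match="time grid"):
            linear_correlation(turb, mass)


class TestSeriesValidation:
    def test_rejects_decreasing_times(self):
        with pytest.raises(ValueError):
            KineticSeries(np.array([0.0, 2.0, 1.0]), np.zeros(3))

    def test_rejects_negative_values(self):
        with pytest.raises(ValueError):
            KineticSeries(np.array([0.0, 1.0, 2.0]), np.array([0.0, -1.0, 2.0]))

    def test_rejects_short_series(self):
        with pytest.raises(ValueError):
            KineticSeries(np.array([0.0, 1.0]), np.array([0.0, 1.0]))
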