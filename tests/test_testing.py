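"""Hypothesis test decisions, calibration and power surfaces."""

import numpy as np
import pytest
from scipy.stats import chi2

from mfbmtest import (
    MfbmModel,
    critical_region,
    gchi2_quantile,
    linear_hurst,
    null_eigenvalues,
    periodic_hurst,
    power_grid,
    preset_linear,
    preset_periodic,
    run_test,
    simulate_mfbm,
)
from mfbmtest.statistic import QuadraticFormSpec
from mfbmtest.testing import _acvf_batch


class TestCriticalRegion:
    def test_identity_cov_lag_zero_reduces_to_scaled_chi2(self):
        # ACVF(0) of N i.i.d. normals is chi2_N / N
        spec = null_eigenvalues(np.eye(10), 0)
        lo, hi = critical_region(spec, tau=0, alpha=0.05)
        assert lo == pytest.approx(chi2.ppf(0.025, 10) / 10, abs=1e-3)
        assert hi == pytest.approx(chi2.ppf(0.975, 10) / 10, abs=1e-3)
        assert lo == pytest.approx(0.32470, abs=1e-3)
        assert hi == pytest.approx(2.04832, abs=1e-3)

    def test_intervals_nest_as_alpha_shrinks(self, linear_model_100):
        spec = null_eigenvalues(linear_model_100, 1)
        prev_lo, prev_hi = critical_region(spec, 1, 0.2)
        for alpha in (0.1, 0.05, 0.01):
            lo, hi = critical_region(spec, 1, alpha)
            assert lo <= prev_lo and hi >= prev_hi
            prev_lo, prev_hi = lo, hi

    def test_monte_carlo_quantile_oracle(self, linear_model_100):
        """Acceptance interval endpoints agree with order statistics of a
        large Monte Carlo sample of the quadratic form."""
        spec = null_eigenvalues(linear_model_100, 1)
        lo, hi = critical_region(spec, 1, 0.05)
        rng = np.random.default_rng(77)
        lam = spec.eigenvalues
        draws = (rng.standard_normal((400_000, lam.size)) ** 2) @ lam
        # 3 SE on the empirical CDF evaluated at the analytic endpoints
        for q, p in ((lo, 0.025), (hi, 0.975)):
            emp = np.mean(draws <= q)
            se = np.sqrt(p * (1 - p) / draws.size)
            assert abs(emp - p) < 3 * se

    def test_invalid_alpha_raises(self, linear_model_100):
        with pytest.raises(ValueError):
            critical_region(linear_model_100, 1, 0.0)


@pytest.fixture(scope="module")
def null_setup(linear_model_100):
    spec = null_eigenvalues(linear_model_100, 1)
    interval = critical_region(spec, 1, 0.05)
    return linear_model_100, spec, interval


class TestRunTest:
    def test_statistic_at_null_median_accepts(self, null_setup):
        model, spec, interval = null_setup
        median = gchi2_quantile(spec, 0.5)
        # build a trajectory whose lag-1 ACVF equals the null median
        x = np.zeros(100)
        x[0] = x[1] = np.sqrt(median * 99.0)
        res = run_test(x, model, tau=1, alpha=0.05,
                       _spec=spec, _interval=interval)
        assert res.statistic == pytest.approx(median, rel=1e-10)
        assert not res.reject
        assert res.p_value == pytest.approx(1.0, abs=1e-6)

    def test_extreme_trajectory_rejected(self, null_setup):
        model, spec, interval = null_setup
        ens = simulate_mfbm(model, n=1, seed=55)
        res = run_test(1e6 * ens.values[0], model, _spec=spec,
                       _interval=interval)
        assert res.reject
        assert res.p_value < 1e-6
        assert res.statistic > res.acceptance_interval[1]

    def test_decision_p_value_coherence(self, null_setup):
        model, spec, interval = null_setup
        ens = simulate_mfbm(model, n=50, seed=56)
        for x in ens.values:
            res = run_test(x, model, _spec=spec, _interval=interval)
            assert res.reject == (res.p_value < 0.05)
            assert 0.0 <= res.p_value <= 1.0

    def test_length_mismatch_raises(self, linear_model_100):
        with pytest.raises(ValueError, match="length"):
            run_test(np.ones(42), linear_model_100)


class TestTypeIError:
    @pytest.mark.parametrize("family", ["linear", "logistic", "periodic"])
    def test_calibration_under_each_null(self, small_models, family):
        """Testing data simulated under the null rejects at ~ alpha."""
        model = small_models[family]
        spec = null_eigenvalues(model, 1)
        lo, hi = critical_region(spec, 1, 0.05)
        ens = simulate_mfbm(model, n=1000, seed=60)
        stats = _acvf_batch(ens.values, 1)
        rate = np.mean((stats < lo) | (stats > hi))
        tol = 3 * np.sqrt(0.05 * 0.95 / 1000)
        assert abs(rate - 0.05) < tol


@pytest.fixture(scope="module")
def linear_null_50():
    return MfbmModel(hurst=preset_linear(50.0), n_points=50)


class TestPowerGrid:
    def test_null_cell_estimates_type_one_error(self, linear_null_50):
        T = 50.0
        grid = power_grid(
            linear_null_50, "linear",
            axis1_values=[0.3 / T], axis2_values=[0.3],
            n_reps=400, seed=5,
        )
        assert grid.valid_mask[0, 0]
        assert abs(grid.power[0, 0] - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 400)

    def test_invalid_cells_masked_without_simulation(self, linear_null_50):
        T = 50.0
        grid = power_grid(
            linear_null_50, "linear",
            axis1_values=[0.3 / T, 0.02], axis2_values=[0.3, 0.99],
            n_reps=10, seed=6,
        )
        # a=0.02 drives H to 0.99 + ... > 1 at t=T; b=0.99 likewise invalid
        assert grid.valid_mask[0, 0]
        assert not grid.valid_mask[1, 1]
        assert not grid.valid_mask[0, 1] or grid.power[0, 1] >= 0
        assert np.isnan(grid.power[~grid.valid_mask]).all()

    def test_masking_matches_analytic_extrema(self, linear_null_50):
        from mfbmtest import validate_hurst

        T = 50.0
        a_vals = np.linspace(-0.02, 0.02, 5)
        b_vals = np.linspace(0.05, 0.95, 5)
        grid = power_grid(
            linear_null_50, "linear", a_vals, b_vals, n_reps=2, seed=7
        )
        for i, a in enumerate(a_vals):
            for j, b in enumerate(b_vals):
                fn = linear_hurst(a, b, T)
                expected = validate_hurst(fn, linear_null_50.grid).valid
                assert grid.valid_mask[i, j] == expected

    def test_power_rises_for_distant_alternatives(self):
        # power grows monotonically as the constant-H alternative's mean
        # moves away from the null's mean H = 0.45, approaching 1
        null = MfbmModel(hurst=preset_linear(200.0), n_points=200)
        grid = power_grid(
            null, "linear",
            axis1_values=[0.0], axis2_values=[0.05, 0.2, 0.45],
            n_reps=200, seed=8,
        )
        p_far, p_mid, p_matched = grid.power[0]
        assert p_far > 0.9
        assert p_far > p_mid > p_matched

    def test_monte_carlo_power_matches_exact_power(self):
        """Dual-route check: the MC rejection fraction per cell agrees with
        the exact power, which is itself a generalized chi-square tail
        probability under the alternative's spectrum."""
        from mfbmtest import gchi2_cdf, periodic_hurst

        null = MfbmModel(hurst=preset_periodic(50.0), n_points=50)
        spec0 = null_eigenvalues(null, 1)
        lo, hi = critical_region(spec0, 1, 0.05)
        grid = power_grid(
            null, "periodic",
            axis1_values=[-0.25, 0.25], axis2_values=[0.45],
            n_reps=300, seed=9,
        )
        for i, a in enumerate([-0.25, 0.25]):
            alt = MfbmModel(hurst=periodic_hurst(a, 0.45, 50.0), n_points=50)
            alt_spec = null_eigenvalues(alt, 1)
            exact = gchi2_cdf(alt_spec, lo) + 1.0 - gchi2_cdf(alt_spec, hi)
            se = np.sqrt(max(exact * (1 - exact), 0.01) / 300)
            assert abs(grid.power[i, 0] - exact) < 3 * se

    def test_grid_reproducible_for_fixed_seed(self, linear_null_50):
        kwargs = dict(
            axis1_values=[0.0, 0.005], axis2_values=[0.4, 0.5],
            n_reps=50, seed=10,
        )
        g1 = power_grid(linear_null_50, "linear", **kwargs)
        g2 = power_grid(linear_null_50, "linear", **kwargs)
        np.testing.assert_array_equal(g1.power, g2.power)

    def test_long_format_export(self, tmp_path, linear_null_50):
        grid = power_grid(
            linear_null_50, "linear",
            axis1_values=[0.0], axis2_values=[0.4, 0.5],
            n_reps=20, seed=11,
        )
        path = tmp_path / "grid.csv"
        grid.to_csv(path)
        import pandas as pd

        df = pd.read_csv(path)
        assert list(df.columns) == ["a", "b", "power", "valid", "n_reps"]
        assert len(df) == 2
        assert path.with_suffix(".csv.manifest.json").exists()

    def test_empty_axes_raise(self, linear_null_50):
        with pytest.raises(ValueError):
            power_grid(linear_null_50, "linear", [], [0.3], n_reps=10, seed=1)
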