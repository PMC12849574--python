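"""Trend models: quadratic volume law, splines, mixed model, AIC comparison."""

import numpy as np
import pytest

from swarmkin import (
    compare_models,
    fit_mixed_speed_density,
    fit_quadratic,
    fit_spline,
    generate_speed_density_rows,
    r_squared,
)
from swarmkin.errors import UnderDeterminedError
from swarmkin.trends import MixedModelFit, gaussian_aic

OSR = np.array([0.0, 50.0, 100.0, 150.0, 200.0])
VOLUMES = np.array([388.4, 305.0, 325.5, 536.3, 612.6])


class TestQuadratic:
    def test_published_group_volume_law(self):
        """Five group-mean volumes against OSR codes give the published
        quadratic coefficients and R^2."""
        fit = fit_quadratic(OSR, VOLUMES)
        assert fit.a == pytest.approx(0.0146, abs=0.001)
        assert fit.b == pytest.approx(-1.5524, abs=0.01)
        assert fit.c == pytest.approx(370.4547, abs=0.5)
        assert fit.r2 == pytest.approx(0.889, abs=0.005)

    def test_exact_parabola(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        fit = fit_quadratic(x, x**2)
        np.testing.assert_allclose([fit.a, fit.b, fit.c], [1.0, 0.0, 0.0], atol=1e-10)
        assert fit.r2 == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(5):
            x = rng.uniform(0, 10, 8)
            y = rng.normal(0, 3, 8)
            design = np.column_stack([x**2, x, np.ones_like(x)])
            oracle = np.linalg.solve(design.T @ design, design.T @ y)
            fit = fit_quadratic(x, y)
            np.testing.assert_allclose(fit.coefficients, oracle, rtol=1e-8)
            # residual orthogonality (normal equations)
            np.testing.assert_allclose(design.T @ fit.residuals, 0.0, atol=1e-8)

    def test_under_determined(self):
        with pytest.raises(UnderDeterminedError):
            fit_quadratic(np.array([1.0, 1.0, 2.0]), np.array([1.0, 2.0, 3.0]))


class TestRSquared:
    def test_perfect_and_mean_prediction(self):
        y = np.array([1.0, 2.0, 4.0])
        assert r_squared(y, y) == 1.0
        assert r_squared(y, np.full(3, y.mean())) == 0.0

    def test_hand_computed_fixture(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        y_hat = np.array([1.5, 1.5, 3.5, 3.5])
        # SSres = 4*0.25 = 1.0; SStot = 5.0
        assert r_squared(y, y_hat) == pytest.approx(1.0 - 1.0 / 5.0, abs=1e-12)

    def test_zero_variance_error(self):
        with pytest.raises(UnderDeterminedError):
            r_squared(np.ones(4), np.ones(4))

    def test_nested_models_monotone(self, rng):
        x = rng.uniform(0, 10, 30)
        y = rng.normal(0, 1, 30) + 0.5 * x
        r2s = [
            r_squared(y, np.polyval(np.polyfit(x, y, deg), x)) for deg in (1, 2, 3)
        ]
        assert np.all(np.diff(r2s) >= -1e-12)


class TestSpline:
    def test_linear_data_at_least_linear_r2(self, rng):
        x = np.linspace(0, 10, 20)
        y = 2.0 * x + 1.0 + rng.normal(0, 0.2, 20)
        lin_r2 = r_squared(y, np.polyval(np.polyfit(x, y, 1), x))
        assert fit_spline(x, y).r2 >= lin_r2 - 1e-9

    def test_interpolating_limit(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])
        fit = fit_spline(x, y, smoothing=1e-12)
        np.testing.assert_allclose(fit.fitted_values, y, atol=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)

    def test_noisy_sine_beats_linear_on_aic(self, rng):
        x = np.linspace(0, 10, 50)
        y = np.sin(x) + rng.normal(0, 0.1, 50)
        sp = fit_spline(x, y)
        # independent AIC oracle from the Gaussian log-likelihood
        lin_fit = np.polyval(np.polyfit(x, y, 1), x)
        lin_aic = gaussian_aic(y, lin_fit, k=3)
        sp_aic_oracle = gaussian_aic(y, sp.predict(x), k=sp.edf + 1)
        assert sp.aic == pytest.approx(sp_aic_oracle, rel=1e-9)
        assert sp.aic < lin_aic

    def test_edf_between_2_and_n(self, rng):
        x = np.linspace(0, 5, 25)
        y = rng.normal(0, 1, 25)
        fit = fit_spline(x, y)
        assert 1.0 < fit.edf < 25.0

    def test_matches_scipy_smoothing_spline(self, rng):
        """Same penalized objective as scipy's natural cubic smoothing
        spline: predictions agree at the data sites for a shared lambda."""
        from scipy.interpolate import make_smoothing_spline

        x = np.linspace(0, 10, 25)
        y = np.sin(x) + rng.normal(0, 0.1, 25)
        lam = 0.05
        ours = fit_spline(x, y, smoothing=lam)
        ref = make_smoothing_spline(x, y, lam=lam)
        np.testing.assert_allclose(ours.predict(x), ref(x), atol=1e-9)

    def test_too_few_points(self):
        with pytest.raises(UnderDeterminedError):
            fit_spline(np.arange(3.0), np.arange(3.0))


class TestMixedModel:
    def test_degenerate_no_replicate_variance_equals_ols(self, rng):
        x = rng.uniform(0, 0.1, 40)
        y = 0.8 - 1.5 * x + rng.normal(0, 0.01, 40)
        rep = np.repeat(["a", "b", "c", "d"], 10)
        mm = fit_mixed_speed_density(x, y, rep)
        ols = np.polyfit(x, y, 1)
        # with no true replicate effect the estimated random-intercept
        # variance collapses and the fit coincides with OLS
        assert mm.random_intercept_var < 1e-4
        assert mm.slope == pytest.approx(ols[0], rel=1e-3)
        assert mm.intercept == pytest.approx(ols[1], rel=1e-3)

    def test_parameter_recovery_within_2se(self):
        rows = generate_speed_density_rows(
            20, slope=-1.5, intercept=0.84, replicate_sd=0.02, n_rows=60
        )
        mm = fit_mixed_speed_density(
            rows["density"], rows["mean_speed"], rows["replicate_id"]
        )
        assert abs(mm.slope - (-1.5)) < 2 * mm.slope_se
        assert mm.slope < 0

    def test_slope_sign_recovered_reliably(self):
        hits = 0
        for seed in range(20):
            rows = generate_speed_density_rows(seed, slope=-1.5, resid_sd=0.02)
            mm = fit_mixed_speed_density(
                rows["density"], rows["mean_speed"], rows["replicate_id"]
            )
            if mm.slope < 0 and abs(mm.slope) / mm.slope_se > 3:
                hits += 1
        assert hits >= 19  # sign recovered in 95%+ of strong-signal datasets

    def test_published_equation_plug_in(self):
        """A model object built from the published coefficients predicts
        0.8376 - 1.4789 * density."""
        mm = MixedModelFit(
            intercept=0.8376, slope=-1.4789, slope_se=0.412,
            random_intercept_var=0.0, resid_var=0.0, pseudo_r2=0.581,
            aic=0.0, n_obs=0, n_groups=0,
        )
        assert mm.predict(0.1) == pytest.approx(0.68971, abs=1e-9)
        assert mm.predict(0.0) == pytest.approx(0.8376)

    def test_single_replicate_falls_back_to_ols(self, rng):
        x = rng.uniform(0, 0.1, 10)
        y = 0.8 - 1.5 * x + rng.normal(0, 0.01, 10)
        mm = fit_mixed_speed_density(x, y, np.repeat("only", 10))
        assert mm.fallback_ols
        assert mm.random_intercept_var == 0.0


class TestCompareModels:
    def test_quadratic_truth_beats_linear(self, rng):
        x = np.linspace(0, 200, 15)
        y = 0.01 * x**2 - 1.5 * x + 370 + rng.normal(0, 5, 15)
        comp = compare_models(x, y)
        names = [e["name"] for e in comp.entries]
        assert names.index("quadratic") < names.index("linear") or names.index(
            "spline"
        ) < names.index("linear")

    def test_five_points_cubic_flagged_saturated(self):
        comp = compare_models(OSR, VOLUMES)
        assert any(s.startswith("cubic") and "saturated" in s for s in comp.skipped)

    def test_tie_preserves_candidate_order(self):
        x = np.linspace(0, 10, 12)
        y = 2.0 * x + 1.0
        comp = compare_models(x, y, candidates=("linear", "linear"))
        assert [e["name"] for e in comp.entries] == ["linear", "linear"]
        assert comp.entries[0]["aic"] == comp.entries[1]["aic"]

    def test_winner_has_lowest_aic(self, rng):
        x = np.linspace(0, 10, 30)
        y = np.sin(x / 2) + rng.normal(0, 0.1, 30)
        comp = compare_models(x, y)
        aics = [e["aic"] for e in comp.entries]
        assert aics == sorted(aics)
        assert comp.entries[0]["name"] == comp.winner
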