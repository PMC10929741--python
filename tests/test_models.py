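"""Statistical core: standardization, LASSO path + LOO-CV, backward
selection, age-based correction, and the varying-coefficient spline model."""

import dataclasses
import warnings

import numpy as np
import pytest

from qaflens import models
from qaflens.config import SplineConfig


class TestStandardize:
    def test_simple_column(self):
        Z, m, s = models.standardize_predictors(np.array([[1.], [2.], [3.]]))
        np.testing.assert_allclose(Z.ravel(), [-1, 0, 1], atol=1e-14)
        assert m[0] == 2.0 and s[0] == 1.0

    def test_idempotent_on_standardized_data(self, rng):
        X = rng.normal(size=(40, 3))
        Z, _, _ = models.standardize_predictors(X)
        Z2, _, _ = models.standardize_predictors(Z)
        np.testing.assert_allclose(Z2, Z, atol=1e-12)

    def test_moments_and_inverse(self, rng):
        X = rng.normal(5, 3, size=(50, 4))
        Z, m, s = models.standardize_predictors(X)
        assert np.all(np.abs(Z.mean(axis=0)) < 1e-12)
        assert np.all(np.abs(Z.std(axis=0, ddof=1) - 1) < 1e-12)
        np.testing.assert_allclose(Z * s + m, X, rtol=1e-12)

    def test_zero_variance_named(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.raises(ValueError, match="lqaf"):
            models.standardize_predictors(X, names=["lqaf", "age"])


@pytest.fixture
def lasso_problem(rng):
    n, p = 30, 4
    Z, _, _ = models.standardize_predictors(rng.normal(size=(n, p)))
    beta = np.array([2.0, -1.0, 0.0, 0.5])
    y = Z @ beta + rng.normal(0, 0.5, n)
    return Z, y


class TestLassoPath:
    def test_all_zero_at_lambda_max(self, lasso_problem):
        Z, y = lasso_problem
        path = models.fit_lasso_path(Z, y)
        assert np.all(path.coef_matrix[0] == 0.0)
        assert path.intercepts[0] == pytest.approx(y.mean(), rel=1e-12)
        assert path.lambda_grid[0] == pytest.approx(models.lambda_max(Z, y))

    def test_smallest_lambda_matches_ols(self, lasso_problem):
        Z, y = lasso_problem
        path = models.fit_lasso_path(Z, y)
        X1 = np.column_stack([np.ones(len(y)), Z])
        bols, *_ = np.linalg.lstsq(X1, y, rcond=None)
        np.testing.assert_allclose(path.coef_matrix[-1], bols[1:], atol=1e-4)

    def test_kkt_conditions_along_the_path(self, lasso_problem):
        Z, y = lasso_problem
        path = models.fit_lasso_path(Z, y)
        for lam, b0, beta in zip(path.lambda_grid, path.intercepts,
                                 path.coef_matrix):
            assert models.kkt_violation(Z, y, b0, beta, lam) <= 1e-8

    def test_matches_sklearn_reference(self, lasso_problem):
        """Independent cross-check against scikit-learn's coordinate-descent
        LASSO (same 1/(2n) objective convention)."""
        from sklearn.linear_model import Lasso
        Z, y = lasso_problem
        path = models.fit_lasso_path(Z, y)
        for i in (10, 50, 90):
            ref = Lasso(alpha=path.lambda_grid[i], tol=1e-14,
                        max_iter=1_000_000).fit(Z, y)
            np.testing.assert_allclose(path.coef_matrix[i], ref.coef_,
                                       atol=1e-6)

    def test_invariant_to_observation_order(self, lasso_problem, rng):
        Z, y = lasso_problem
        perm = rng.permutation(len(y))
        a = models.fit_lasso_path(Z, y)
        b = models.fit_lasso_path(Z[perm], y[perm])
        np.testing.assert_allclose(a.coef_matrix, b.coef_matrix, atol=1e-8)

    def test_warm_and_cold_starts_agree(self, lasso_problem):
        Z, y = lasso_problem
        path = models.fit_lasso_path(Z, y)
        for i in (20, 70):
            b0, beta = models._cd_solve(Z, y, path.lambda_grid[i],
                                        np.zeros(Z.shape[1]))
            np.testing.assert_allclose(path.coef_matrix[i], beta, atol=1e-8)

    def test_nonfinite_rejected(self, lasso_problem):
        Z, y = lasso_problem
        y = y.copy()
        y[0] = np.nan
        with pytest.raises(ValueError):
            models.fit_lasso_path(Z, y)


class TestLooCv:
    def test_perfect_signal_selected(self, rng):
        Z, _, _ = models.standardize_predictors(rng.normal(size=(25, 3)))
        y = 2.0 * Z[:, 0]
        path = models.fit_lasso_path(Z, y, names=["z1", "z2", "z3"])
        lam, selected, cv_r2 = models.loo_cv_select(Z, y, path)
        assert "z1" in selected and cv_r2 > 0.99

    def test_matches_bruteforce_refit_loop(self, lasso_problem):
        Z, y = lasso_problem
        path = models.fit_lasso_path(Z, y)
        models.loo_cv_select(Z, y, path)
        n = len(y)
        for i in (5, 40, 95):
            lam = path.lambda_grid[i]
            sq = 0.0
            for k in range(n):
                mask = np.ones(n, bool)
                mask[k] = False
                b0, beta = models._cd_solve(Z[mask], y[mask], lam,
                                            np.zeros(Z.shape[1]))
                sq += (y[k] - b0 - Z[k] @ beta) ** 2
            assert path.loocv_error[i] == pytest.approx(sq / n, abs=1e-10)

    def test_too_few_observations(self):
        Z = np.array([[1.0], [-1.0]])
        y = np.array([1.0, -1.0])
        with pytest.raises(ValueError):
            models.loo_cv_select(Z, y, models.LassoPath(
                np.array([1.0]), np.zeros((1, 1)), np.zeros(1)))


class TestBackwardSelect:
    def test_pure_noise_predictor_eliminated_first(self, rng):
        n = 60
        x1 = rng.normal(size=n)
        noise = rng.normal(size=n)
        y = 3 * x1 + rng.normal(0, 0.5, n)
        out = models.backward_select(np.column_stack([x1, noise]), y,
                                     ["signal", "noise"])
        assert out["elimination_order"][:1] == ["noise"]
        assert out["final_set"] == ["signal"]

    def test_each_step_matches_exhaustive_search(self, rng):
        n, p = 40, 3
        X = rng.normal(size=(n, p))
        y = X[:, 0] + 0.1 * X[:, 1] + rng.normal(0, 1.0, n)
        out = models.backward_select(X, y, ["a", "b", "c"])
        names = ["a", "b", "c"]
        active = list(range(p))
        for entry in out["log"][1:]:
            cand = {j: models._ols_loo_mse(
                X[:, [k for k in active if k != j]], y) for j in active}
            best = min(cand, key=lambda j: cand[j])
            assert names[best] == entry["removed"]
            active.remove(best)

    def test_needs_two_predictors(self, rng):
        with pytest.raises(ValueError):
            models.backward_select(rng.normal(size=(10, 1)),
                                   rng.normal(size=10))


class TestAgeCorrection:
    def test_pseudophakic_unchanged(self):
        spec = models.AgeCorrectionSpec()
        assert models.age_based_estimate(100.0, 70.0, False, spec) == 100.0

    def test_identity_factor(self):
        spec = models.AgeCorrectionSpec(c0=0.0, c1=0.0)
        assert models.age_based_estimate(123.0, 50.0, True, spec) == 123.0

    def test_monotone_in_age(self):
        spec = models.AgeCorrectionSpec()
        ages = np.linspace(20, 90, 71)
        corrected = models.age_based_estimate(np.full(71, 100.0), ages,
                                              np.ones(71, bool), spec)
        assert np.all(np.diff(corrected) >= 0)
        assert np.all(corrected >= 100.0)  # CF >= 1

    def test_table_form_interpolates(self):
        spec = models.AgeCorrectionSpec(form="table",
                                        table_ages=np.array([20.0, 80.0]),
                                        table_factors=np.array([1.0, 2.0]))
        assert spec.factor(50.0) == pytest.approx(1.5)

    def test_age_domain_enforced(self):
        with pytest.raises(ValueError):
            models.AgeCorrectionSpec().factor(110.0)


@pytest.fixture
def spline_data(rng):
    n = 200
    age = rng.uniform(25, 85, n)
    lqaf = rng.uniform(3, 27, n)
    pns = rng.integers(0, 6, n).astype(float)
    y = (100 + 1.2 * age - 2.0 * lqaf + 0.05 * lqaf * age - 4.0 * pns
         + rng.normal(0, 8, n))
    return age, lqaf, pns, y


class TestSplineModel:
    def test_penalty_limit_equals_linear_ols(self, spline_data):
        """With all smoothing parameters pinned at a huge value the penalties
        leave only their null space (linear functions of age), so the fit
        must match OLS on [1, age, lqaf, lqaf*age, pns, pns*age]."""
        age, lqaf, pns, y = spline_data
        cfg = SplineConfig(gcv_grid_size=1, gcv_log10_min=9.0,
                           gcv_log10_max=9.0, gcv_passes=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = models.fit_spline_model(age, lqaf, pns, y, cfg)
        X = np.column_stack([np.ones(len(y)), age, lqaf, lqaf * age,
                             pns, pns * age])
        bols, *_ = np.linalg.lstsq(X, y, rcond=None)
        a0, a1 = 40.0, 80.0
        # f2, f3 are linear in the limit: recover slope and intercept
        for term, ic, sc in (("s(age):lqaf", 2, 3), ("s(age):pns", 4, 5)):
            f = models.evaluate_term(fit, term, np.array([a0, a1]))
            slope = (f[1] - f[0]) / (a1 - a0)
            intercept = f[0] - slope * a0
            assert slope == pytest.approx(bols[sc], abs=1e-3)
            assert intercept == pytest.approx(bols[ic], abs=1e-3)
        f1 = models.evaluate_term(fit, "s(age)", np.array([a0, a1]))
        slope1 = (f1[1] - f1[0]) / (a1 - a0)
        assert slope1 == pytest.approx(bols[1], abs=1e-3)
        # intercept absorbs the sum-to-zero centering of f1
        assert fit.intercept + (f1[0] - slope1 * a0) == pytest.approx(
            bols[0], abs=1e-3 * max(1.0, abs(bols[0])))

    def test_predictions_reproduce_fitted_values(self, spline_data):
        age, lqaf, pns, y = spline_data
        fit = models.fit_spline_model(age, lqaf, pns, y)
        pred = models.predict_qaf(fit, age, lqaf, pns)
        np.testing.assert_allclose(pred, fit.fitted, atol=1e-10)

    def test_zero_scores_isolate_age_smooth(self, spline_data):
        age, lqaf, pns, y = spline_data
        fit = models.fit_spline_model(age, lqaf, pns, y)
        at = np.array([45.0, 60.0, 75.0])
        pred = models.predict_qaf(fit, at, np.zeros(3), np.zeros(3))
        expect = fit.intercept + models.evaluate_term(fit, "s(age)", at)
        np.testing.assert_allclose(pred, expect, atol=1e-10)

    def test_manual_basis_evaluation(self, spline_data):
        from scipy.interpolate import BSpline
        age, lqaf, pns, y = spline_data
        fit = models.fit_spline_model(age, lqaf, pns, y)
        pts = np.linspace(30, 80, 5)
        B = BSpline.design_matrix(pts, fit.knots, fit.degree).toarray()
        manual = (fit.intercept + B @ fit.constraint @ fit.coef_f1
                  + 2.0 * (B @ fit.coef_f2) + 1.0 * (B @ fit.coef_f3))
        pred = models.predict_qaf(fit, pts, np.full(5, 2.0), np.ones(5))
        np.testing.assert_allclose(pred, manual, atol=1e-10)

    def test_residuals_orthogonal_to_null_space(self, spline_data):
        age, lqaf, pns, y = spline_data
        fit = models.fit_spline_model(age, lqaf, pns, y)
        r = y - fit.fitted
        N = np.column_stack([np.ones(len(y)), age, lqaf, lqaf * age,
                             pns, pns * age])
        for col in N.T:
            cosang = abs(r @ col) / (np.linalg.norm(r) * np.linalg.norm(col))
            assert cosang < 1e-8

    def test_edf_bounded_by_basis_dimension(self, spline_data):
        age, lqaf, pns, y = spline_data
        fit = models.fit_spline_model(age, lqaf, pns, y)
        dims = {"s(age)": 7, "s(age):lqaf": 8, "s(age):pns": 8}
        for term, dim in dims.items():
            assert 0 < fit.edf[term] <= dim + 1e-8
        assert 0.0 <= fit.deviance_explained <= 1.0

    def test_report_layout_has_all_terms(self, spline_data):
        age, lqaf, pns, y = spline_data
        fit = models.fit_spline_model(age, lqaf, pns, y)
        assert np.isfinite(fit.intercept_se) and np.isfinite(fit.intercept_t)
        for term in fit.TERMS:
            tt = fit.term_tests[term]
            assert set(tt) == {"edf", "ref_df", "F", "p"}
            assert 0.0 <= tt["p"] <= 1.0

    def test_degenerate_design_rejected(self, rng):
        n = 60
        age = rng.uniform(30, 80, n)
        lqaf = rng.uniform(3, 27, n)
        y = rng.normal(size=n)
        with pytest.raises(ValueError, match="degenerate"):
            models.fit_spline_model(age, lqaf, np.zeros(n), y)

    def test_extrapolation_warns(self, spline_data):
        age, lqaf, pns, y = spline_data
        fit = models.fit_spline_model(age, lqaf, pns, y)
        with pytest.warns(UserWarning, match="training range"):
            models.predict_qaf(fit, 110.0, 10.0, 1.0)

    def test_unfitted_model_raises(self, spline_data):
        age, lqaf, pns, y = spline_data
        fit = models.fit_spline_model(age, lqaf, pns, y)
        broken = dataclasses.replace(fit, coef_f1=None)
        with pytest.raises(RuntimeError):
            models.predict_qaf(broken, 50.0, 10.0, 1.0)

    def test_small_sample_rejected(self, rng):
        with pytest.raises(ValueError):
            models.fit_spline_model(rng.uniform(30, 80, 10),
                                    rng.uniform(3, 27, 10),
                                    rng.integers(0, 6, 10).astype(float),
                                    rng.normal(size=10))
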