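"""Null-model fitting, weighted projection and covariance estimators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import erfc

from gescan import (
    GAUSSIAN,
    BINOMIAL_LOGIT,
    NullModelFit,
    PhenotypeTable,
    chisq_pvalue,
    fit_null_model,
    model_based_covariance,
    project_out_covariates,
    robust_covariance,
)
from conftest import full_interaction_design, random_gaussian_dataset


def _intercept_table(y):
    n = len(y)
    return PhenotypeTable(
        sample_ids=np.arange(n).astype(str),
        y=np.asarray(y, dtype=float),
        X=np.ones((n, 1)),
        covariate_names=["intercept"],
    )


def _manual_gaussian_fit(X, weights=None, residuals=None, dispersion=1.0):
    """Assemble a NullModelFit directly for covariance-estimator unit tests."""
    n, p = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    r = np.zeros(n) if residuals is None else np.asarray(residuals, dtype=float)
    xtwx = X.T @ (w[:, None] * X)
    return NullModelFit(
        family=GAUSSIAN, beta_X=np.zeros(p), mu=np.zeros(n), weights=w,
        residuals=r, dispersion=dispersion, xtwx_inv=np.linalg.inv(xtwx),
        X=X, converged=True, n_iter=1,
    )


class TestFitNullModel:
    def test_constant_outcome_gaussian(self):
        fit = fit_null_model(_intercept_table(np.full(8, 5.0)), "gaussian")
        assert fit.beta_X == pytest.approx([5.0])
        assert np.allclose(fit.residuals, 0)
        assert fit.dispersion == pytest.approx(0.0)

    def test_balanced_binary_logit(self):
        y = np.array([0.0] * 10 + [1.0] * 10)
        fit = fit_null_model(_intercept_table(y), "binomial")
        assert fit.beta_X == pytest.approx([0.0], abs=1e-8)
        assert np.allclose(fit.mu, 0.5)
        assert np.allclose(fit.weights, 0.25)
        assert fit.converged

    def test_gaussian_matches_normal_equations(self, rng):
        n = 50
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        y = rng.standard_normal(n)
        pheno = PhenotypeTable(
            sample_ids=np.arange(n).astype(str), y=y, X=X,
            covariate_names=["intercept", "a", "b"],
        )
        fit = fit_null_model(pheno, "gaussian")
        oracle = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(fit.beta_X, oracle, atol=1e-10)

    def test_score_equations_hold_at_convergence(self, rng):
        n = 400
        x = rng.standard_normal(n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.3 + 0.8 * x)))).astype(float)
        pheno = PhenotypeTable.from_arrays(y, {"x": x})
        fit = fit_null_model(pheno, "binomial")
        score = pheno.X.T @ (pheno.y - fit.mu)
        assert np.abs(score).max() < 1e-8

    def test_rank_deficiency_names_collinear_columns(self, rng):
        n = 30
        x = rng.standard_normal(n)
        with pytest.raises(ValueError, match="collinear columns: \\['(x|dup)'\\]"):
            PhenotypeTable.from_arrays(rng.standard_normal(n), {"x": x, "dup": 2 * x})

    def test_binomial_requires_both_classes(self):
        with pytest.raises(ValueError, match="both classes"):
            fit_null_model(_intercept_table(np.r_[np.ones(9), 0.5]), "binomial")

    def test_nonconvergence_returns_last_iterate(self, rng):
        n = 200
        x = rng.standard_normal(n)
        y = (rng.random(n) < 0.5).astype(float)
        pheno = PhenotypeTable.from_arrays(y, {"x": x})
        with pytest.warns(RuntimeWarning, match="did not converge"):
            fit = fit_null_model(pheno, "binomial", tol=1e-16, max_iter=1)
        assert not fit.converged
        assert fit.n_iter == 1
        assert np.all(np.isfinite(fit.beta_X))


class TestProjection:
    def test_covariate_column_projects_to_zero(self, rng):
        pheno, g, _ = random_gaussian_dataset(rng, 40, 1, 0)
        fit = fit_null_model(pheno, "gaussian")
        out = project_out_covariates(pheno.X[:, 1], fit)
        assert np.abs(out).max() < 1e-10

    def test_orthogonal_matrix_unchanged(self, rng):
        n = 60
        X = np.ones((n, 1))
        y = rng.standard_normal(n)
        fit = fit_null_model(_intercept_table(y), "gaussian")
        M = rng.standard_normal((n, 2))
        M -= M.mean(axis=0)  # orthogonal to the intercept
        np.testing.assert_allclose(project_out_covariates(M, fit, X), M, atol=1e-12)

    def test_matches_dense_projection_matrix(self, rng):
        n = 20
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        w = rng.uniform(0.2, 2.0, size=n)
        M = rng.standard_normal((n, 3))
        fit = _manual_gaussian_fit(X, weights=w)
        P = X @ np.linalg.inv(X.T @ (w[:, None] * X)) @ X.T @ np.diag(w)
        oracle = (np.eye(n) - P) @ M
        np.testing.assert_allclose(project_out_covariates(M, fit, X), oracle, atol=1e-10)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_idempotent_and_w_orthogonal(self, seed):
        r = np.random.default_rng(seed)
        n = 25
        X = np.column_stack([np.ones(n), r.standard_normal(n)])
        w = r.uniform(0.1, 3.0, size=n)
        M = r.standard_normal((n, 2))
        fit = _manual_gaussian_fit(X, weights=w)
        Mt = project_out_covariates(M, fit, X)
        assert np.abs(X.T @ (w[:, None] * Mt)).max() < 1e-8
        np.testing.assert_allclose(project_out_covariates(Mt, fit, X), Mt, atol=1e-9)

    def test_dimension_mismatch_raises(self, rng):
        pheno, g, _ = random_gaussian_dataset(rng, 30, 1, 0)
        fit = fit_null_model(pheno, "gaussian")
        with pytest.raises(ValueError, match="row mismatch"):
            project_out_covariates(np.zeros(10), fit)


class TestCovarianceEstimators:
    def test_orthonormal_design_gives_identity(self, rng):
        n = 64
        D, _ = np.linalg.qr(rng.standard_normal((n, 3)))
        fit = _manual_gaussian_fit(np.ones((n, 1)), dispersion=1.0)
        np.testing.assert_allclose(model_based_covariance(D, fit), np.eye(3), atol=1e-10)

    def test_linear_in_dispersion(self, rng):
        n = 50
        D = rng.standard_normal((n, 2))
        f1 = _manual_gaussian_fit(np.ones((n, 1)), dispersion=0.7)
        f2 = _manual_gaussian_fit(np.ones((n, 1)), dispersion=1.4)
        np.testing.assert_allclose(
            model_based_covariance(D, f2), 2 * model_based_covariance(D, f1)
        )

    def test_matches_full_refit_block_via_fwl(self, rng):
        """(D~'D~)^-1 equals the interaction block of the full-design inverse."""
        pheno, g, cfg = random_gaussian_dataset(rng, 100, 2, 1)
        fit = fit_null_model(pheno, "gaussian")
        from gescan import build_variant_design

        D = build_variant_design(g, pheno, cfg)
        Dp = project_out_covariates(D, fit)
        Z = full_interaction_design(pheno, g, cfg)
        p = pheno.X.shape[1]
        block = np.linalg.inv(Z.T @ Z)[p:, p:]
        np.testing.assert_allclose(
            model_based_covariance(Dp, fit), fit.dispersion * block, atol=1e-8
        )

    def test_equal_magnitude_residuals_reduce_to_model_based(self, rng):
        n = 40
        sigma = 1.7
        D = rng.standard_normal((n, 2))
        e = sigma * rng.choice([-1.0, 1.0], size=n)
        fit = _manual_gaussian_fit(np.ones((n, 1)), residuals=e, dispersion=sigma**2)
        np.testing.assert_allclose(
            robust_covariance(D, fit), model_based_covariance(D, fit), atol=1e-10
        )

    def test_quadratic_in_residuals(self, rng):
        n = 30
        D = rng.standard_normal((n, 2))
        e = rng.standard_normal(n)
        f1 = _manual_gaussian_fit(np.ones((n, 1)), residuals=e)
        f2 = _manual_gaussian_fit(np.ones((n, 1)), residuals=2 * e)
        np.testing.assert_allclose(robust_covariance(D, f2), 4 * robust_covariance(D, f1))

    def test_matches_textbook_hc0_on_full_design(self, rng):
        """With full-model residuals, the sandwich equals HC0 of the OLS refit."""
        sm = pytest.importorskip("statsmodels.api")
        pheno, g, cfg = random_gaussian_dataset(rng, 200, 1, 0)
        # heteroskedastic noise
        e0 = pheno.X[:, pheno.column_index(["e0"])[0]]
        pheno.y = pheno.y + np.abs(e0) * rng.standard_normal(200)
        fit = fit_null_model(pheno, "gaussian")
        from gescan import build_variant_design

        D = build_variant_design(g, pheno, cfg)
        Dp = project_out_covariates(D, fit)
        beta = np.linalg.solve(Dp.T @ Dp, Dp.T @ fit.residuals)
        resid_full = fit.residuals - Dp @ beta
        V = robust_covariance(Dp, fit, residuals=resid_full)
        Z = full_interaction_design(pheno, g, cfg)
        ols = sm.OLS(pheno.y, Z).fit(cov_type="HC0")
        p = pheno.X.shape[1]
        oracle = ols.cov_params()[p:, p:]
        np.testing.assert_allclose(V, oracle, rtol=1e-6)

    def test_robust_matches_model_based_in_expectation(self, rng):
        """Under homoskedastic gaussian noise the two estimators agree on average."""
        n = 200
        X = np.ones((n, 1))
        D = rng.standard_normal((n, 2))
        Dp = D - D.mean(axis=0)
        tot_r = np.zeros((2, 2))
        tot_m = np.zeros((2, 2))
        n_sims = 500
        for _ in range(n_sims):
            y = rng.standard_normal(n)
            pheno = PhenotypeTable(
                sample_ids=np.arange(n).astype(str), y=y, X=X,
                covariate_names=["intercept"],
            )
            fit = fit_null_model(pheno, "gaussian")
            tot_r += robust_covariance(Dp, fit)
            tot_m += model_based_covariance(Dp, fit)
        ratio = tot_r / tot_m
        assert np.all(ratio > 0.9) and np.all(ratio < 1.1)


class TestChisqPvalue:
    def test_zero_statistic_is_one(self):
        assert chisq_pvalue(0.0, 1) == 1.0
        assert chisq_pvalue(0.0, 5) == 1.0

    def test_genomewide_threshold_statistic(self):
        # oracle: two-sided normal tail of |z| = sqrt(29.7168) via erfc
        z = np.sqrt(29.7168)
        oracle = float(erfc(z / np.sqrt(2)))
        assert chisq_pvalue(29.7168, 1) == pytest.approx(oracle, rel=1e-10)
        assert oracle == pytest.approx(5.0e-8, rel=1e-3)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        st.floats(0, 200), st.floats(0, 200), st.integers(1, 10)
    )
    def test_monotone_nonincreasing(self, s1, s2, df):
        lo, hi = sorted([s1, s2])
        assert chisq_pvalue(lo, df) >= chisq_pvalue(hi, df)

    def test_extreme_statistic_never_underflows_to_zero(self):
        p = chisq_pvalue(1500.0, 1)
        assert 0 < p < 1e-300

    def test_negative_statistic_handling(self):
        with pytest.warns(RuntimeWarning, match="clamping"):
            assert chisq_pvalue(-1e-12, 1) == 1.0
        with pytest.raises(ValueError, match="negative"):
            chisq_pvalue(-0.5, 1)


class TestScoreStatistic:
    def test_gaussian_score_equals_anova_f_numerator(self, rng):
        """For gaussian with one projected column, the score chi-square is
        (D~'r)^2 / (phi * D~'D~), the squared score z-statistic."""
        from gescan import fit_null_model, project_out_covariates, score_statistic

        pheno, g, _ = random_gaussian_dataset(rng, 120, 1, 0, effect=0.0)
        fit = fit_null_model(pheno, "gaussian")
        Dp = project_out_covariates(g, fit).reshape(-1, 1)
        stat = score_statistic(Dp, fit)
        oracle = float(Dp[:, 0] @ fit.residuals) ** 2 / (
            fit.dispersion * float(Dp[:, 0] @ Dp[:, 0])
        )
        assert stat == pytest.approx(oracle, rel=1e-10)

    def test_robust_score_variance_uses_squared_residuals(self, rng):
        from gescan import fit_null_model, project_out_covariates, score_statistic

        pheno, g, _ = random_gaussian_dataset(rng, 120, 1, 0, effect=0.0)
        fit = fit_null_model(pheno, "gaussian")
        Dp = project_out_covariates(g, fit).reshape(-1, 1)
        stat = score_statistic(Dp, fit, robust=True)
        num = float(Dp[:, 0] @ fit.residuals) ** 2
        den = float((Dp[:, 0] ** 2) @ (fit.residuals**2))
        assert stat == pytest.approx(num / den, rel=1e-10)
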