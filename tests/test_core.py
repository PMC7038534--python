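"""Linear predictor algebra, penalized likelihood arithmetic, ALS behaviour
(monotonicity, shrinkage, determinism) and the half-step ridge solver."""

import numpy as np
import pytest

from hiscom_pca import (
    als_fit,
    initialize,
    linear_predictor,
    pathway_scores,
    penalized_loglik,
    ridge_glm_solve,
)
from hiscom_pca.core import HisCoMFit, _LOG2PI

from conftest import make_random_design


def fit_with(design, **kw):
    beta0 = kw.pop("beta0", 0.0)
    return HisCoMFit(
        beta0=beta0,
        beta=np.asarray(kw.pop("beta"), float),
        weights=np.asarray(kw.pop("weights"), float),
        covariate_coefs=np.asarray(
            kw.pop("covariate_coefs", np.zeros(design.covariates.shape[1])),
            float),
        lambda_g=kw.pop("lambda_g", 0.0),
        lambda_p=kw.pop("lambda_p", 0.0),
        family=kw.pop("family", "gaussian"),
        dispersion=kw.pop("dispersion", 1.0),
        objective_trace=np.zeros(1), converged=True, n_iter=0,
    )


class TestLinearPredictor:
    def test_zero_weights_reduce_to_intercept_plus_covariates(self):
        design = make_random_design(1, n=20, K=2, n_covariates=2)
        a = np.array([0.5, -1.0])
        fit = fit_with(design, beta0=0.7, beta=[3.0, -2.0],
                       weights=np.zeros(design.n_columns), covariate_coefs=a)
        np.testing.assert_allclose(linear_predictor(design, fit),
                                   0.7 + design.covariates @ a, atol=1e-12)

    def test_single_block_arithmetic(self):
        design = make_random_design(2, n=5, K=1, genes_per_block=1)
        design.matrix[:, 0] = 1.0  # g column of ones
        fit = fit_with(design, beta0=0.0, beta=[3.0], weights=[2.0])
        np.testing.assert_allclose(linear_predictor(design, fit), 6.0)

    def test_bilinear_scale_invariance(self):
        design = make_random_design(3, n=30, K=2)
        rng = np.random.default_rng(0)
        w = rng.standard_normal(design.n_columns)
        beta = rng.standard_normal(2)
        eta1 = linear_predictor(design, fit_with(design, beta=beta, weights=w))
        eta2 = linear_predictor(design,
                                fit_with(design, beta=beta / 5.0,
                                         weights=5.0 * w))
        np.testing.assert_allclose(eta1, eta2, atol=1e-10)

    def test_dimension_mismatch_raises(self):
        design = make_random_design(4, n=10, K=2)
        fit = fit_with(design, beta=[1.0], weights=np.zeros(design.n_columns))
        with pytest.raises(ValueError, match="dimensions"):
            linear_predictor(design, fit)


class TestPenalizedLoglik:
    def test_binomial_null_model_closed_form(self):
        design = make_random_design(5, n=40, K=2)
        rng = np.random.default_rng(5)
        y = (rng.random(40) < 0.3).astype(float)
        ybar = y.mean()
        fit = fit_with(design, beta0=np.log(ybar / (1 - ybar)),
                       beta=np.zeros(2), weights=np.zeros(design.n_columns),
                       family="binomial")
        expected = 40 * (ybar * np.log(ybar) + (1 - ybar) * np.log(1 - ybar))
        assert penalized_loglik(design, fit, y) == pytest.approx(expected,
                                                                 abs=1e-10)

    def test_pathway_penalty_arithmetic(self):
        design = make_random_design(6, n=15, K=2)
        y = np.zeros(15)
        w = np.zeros(design.n_columns)
        base = penalized_loglik(
            design, fit_with(design, beta=[2.0, 0.0], weights=w, lambda_p=0.0), y)
        plus = penalized_loglik(
            design, fit_with(design, beta=[2.0, 0.0], weights=w, lambda_p=1.0), y)
        assert base - plus == pytest.approx(2.0, abs=1e-10)  # 0.5 * 1 * 4

    def test_gaussian_perfect_fit(self):
        design = make_random_design(7, n=25, K=1)
        w = np.zeros(design.n_columns)
        fit = fit_with(design, beta0=1.5, beta=[0.0], weights=w,
                       dispersion=1.0)
        y = np.full(25, 1.5)
        assert penalized_loglik(design, fit, y) == pytest.approx(
            -25 / 2 * _LOG2PI, abs=1e-10)


class TestInitialize:
    def test_equal_weights_unit_block_norm(self):
        design = make_random_design(8, n=10, K=1, genes_per_block=4)
        init = initialize(design, np.zeros(10), "gaussian")
        np.testing.assert_allclose(init["weights"], 0.5)

    def test_binomial_null_intercept(self):
        design = make_random_design(9, n=8, K=1)
        y = np.array([1.0, 0, 0, 0, 1, 0, 0, 0])  # mean 0.25
        init = initialize(design, y, "binomial")
        assert init["beta0"] == pytest.approx(np.log(1.0 / 3.0))

    def test_random_init_seeded_determinism(self):
        design = make_random_design(10, n=50, K=3)
        rng = np.random.default_rng(99)
        y = rng.standard_normal(50)
        f1 = als_fit(design, y, init="random", seed=4, lambda_g=1, lambda_p=1)
        f2 = als_fit(design, y, init="random", seed=4, lambda_g=1, lambda_p=1)
        np.testing.assert_array_equal(f1.weights, f2.weights)
        np.testing.assert_array_equal(f1.beta, f2.beta)


class TestALSFit:
    def test_large_pathway_penalty_shrinks_beta_to_zero(self):
        design = make_random_design(11, n=80, K=2)
        rng = np.random.default_rng(1)
        y = design.matrix @ rng.standard_normal(design.n_columns) \
            + rng.standard_normal(80)
        fit = als_fit(design, y, lambda_g=1.0, lambda_p=1e8)
        assert np.linalg.norm(fit.beta) < 1e-3
        eta = linear_predictor(design, fit)
        np.testing.assert_allclose(eta, fit.beta0, atol=1e-2)

    @pytest.mark.parametrize("family", ["gaussian", "binomial"])
    def test_objective_monotone_over_half_steps(self, family):
        design = make_random_design(12, n=100, K=3, n_covariates=1)
        rng = np.random.default_rng(2)
        y = design.matrix[:, 0] + rng.standard_normal(100)
        if family == "binomial":
            y = (y > np.median(y)).astype(float)
        fit = als_fit(design, y, family=family, lambda_g=0.5, lambda_p=0.5)
        diffs = np.diff(fit.objective_trace)
        slack = 1e-8 if family == "gaussian" else 1e-6
        assert diffs.min() > -slack
        assert fit.objective_trace[-1] >= fit.objective_trace[0]

    def test_shrinkage_monotone_in_lambda_p(self):
        """At fixed converged weights, the pathway-coefficient refit shrinks
        monotonically as lambda_p grows."""
        design = make_random_design(13, n=120, K=4)
        rng = np.random.default_rng(3)
        y = design.matrix @ rng.standard_normal(design.n_columns) \
            + rng.standard_normal(120)
        base = als_fit(design, y, lambda_g=1.0, lambda_p=1.0)
        S = pathway_scores(design, base.weights)
        X = np.hstack([np.ones((120, 1)), S])
        norms = []
        for lam in (0.1, 1.0, 10.0, 100.0):
            pen = np.r_[0.0, np.full(design.K, lam)]
            theta = ridge_glm_solve(X, y, pen, "gaussian")
            norms.append(float(theta[1:] @ theta[1:]))
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))

    def test_permutation_safety_design_unchanged(self):
        design = make_random_design(14, n=60, K=2)
        rng = np.random.default_rng(4)
        y = rng.standard_normal(60)
        before = design.matrix.copy()
        cov_before = design.covariates.copy()
        als_fit(design, y[rng.permutation(60)], lambda_g=1, lambda_p=1)
        als_fit(design, y, lambda_g=1, lambda_p=1)
        np.testing.assert_array_equal(design.matrix, before)
        np.testing.assert_array_equal(design.covariates, cov_before)

    def test_sign_convention_largest_weight_positive(self):
        design = make_random_design(15, n=90, K=3)
        rng = np.random.default_rng(6)
        y = design.matrix @ rng.standard_normal(design.n_columns) \
            + 0.5 * rng.standard_normal(90)
        fit = als_fit(design, y, lambda_g=1, lambda_p=1)
        for k in range(design.K):
            wk = fit.weights[design.block_columns(k)]
            assert wk[np.argmax(np.abs(wk))] > 0

    def test_penalty_rebalance_equalises_layers(self):
        """At convergence lambda_g ||w_k||^2 = lambda_p beta_k^2 per block
        (the scale split the two penalties jointly pin down)."""
        design = make_random_design(16, n=100, K=2)
        rng = np.random.default_rng(8)
        y = design.matrix[:, 0] - design.matrix[:, 3] \
            + rng.standard_normal(100)
        lg, lp = 2.0, 0.5
        fit = als_fit(design, y, lambda_g=lg, lambda_p=lp)
        for k in range(design.K):
            wk = fit.weights[design.block_columns(k)]
            assert lg * float(wk @ wk) == pytest.approx(
                lp * fit.beta[k] ** 2, rel=1e-3)

    def test_singular_at_zero_penalty_advises_ridge(self):
        design = make_random_design(17, n=40, K=1, genes_per_block=2)
        design.matrix[:, 1] = design.matrix[:, 0]  # exact collinearity
        y = np.random.default_rng(10).standard_normal(40)
        with pytest.raises((ValueError, np.linalg.LinAlgError)):
            als_fit(design, y, lambda_g=0.0, lambda_p=0.0)
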