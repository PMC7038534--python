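"""The hierarchical structural component GLM and its ALS estimator.

Model
-----
For subject ``j`` with phenotype ``y_j`` from an exponential-family
distribution (gaussian or binomial), the linear predictor is

    eta_j = beta0 + sum_k ( sum_t sum_i g_ktij * w_kti ) * beta_k + z_j' a

where ``g_kti`` is the i-th selected PC of gene ``t`` in pathway ``k``,
``w_kti`` its gene-level weight, ``beta_k`` the pathway coefficient and ``a``
unpenalised covariate coefficients.  Estimation maximises the penalized
log-likelihood

    phi = sum_j log p(y_j; eta_j) - (1/2) lambda_g sum w^2
                                  - (1/2) lambda_p sum beta^2

by alternating least squares: with the weights fixed, the pathway scores
``S_k = sum_{t,i} g_kti w_kti`` are ordinary regressors and ``(beta0, beta,
a)`` solve a ridge GLM with penalty ``lambda_p`` on ``beta`` only; with the
pathway coefficients fixed, the predictor is linear in ``w`` with effective
regressors ``g_kti * beta_k`` and ``(beta0, w, a)`` solve a ridge GLM with
penalty ``lambda_g`` on ``w`` only.  For the gaussian family each half-step
is a closed-form weighted-least-squares solve; for the binomial family it is
damped Newton (IRLS with step halving), so the objective never decreases
across half-steps.

During optimisation the gaussian log-likelihood is evaluated at unit
dispersion (which has the same maximiser); the residual mean square is
estimated once at convergence and stored as ``dispersion``.

The ``(w_k, beta_k) <-> (-w_k, -beta_k)`` sign indeterminacy of each block is
resolved after convergence by making the largest-|w| entry in every block
positive.  The scale split between ``w_k`` and ``beta_k`` is pinned by the
two ridge penalties themselves (with ``lambda_g = lambda_p = 0`` and a single
block only the product ``w * beta`` is identified).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import expit

from .genepc import HierarchicalDesign

__all__ = [
    "FitConfig",
    "HisCoMFit",
    "initialize",
    "als_fit",
    "linear_predictor",
    "pathway_scores",
    "penalized_loglik",
    "ridge_glm_solve",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class FitConfig:
    """Everything needed to reproduce one ALS fit."""

    family: str = "gaussian"
    lambda_g: float = 1.0
    lambda_p: float = 1.0
    tol: float = 1e-5
    max_iter: int = 100
    init: str = "equal"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "binomial"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.lambda_g < 0 or self.lambda_p < 0:
            raise ValueError("ridge parameters must be non-negative")


@dataclass
class HisCoMFit:
    """Fitted parameters and optimisation trace of one ALS run."""

    beta0: float
    beta: np.ndarray              # (K,) pathway coefficients
    weights: np.ndarray           # (P,) gene-PC weights, design column order
    covariate_coefs: np.ndarray   # (c,) unpenalised
    lambda_g: float
    lambda_p: float
    family: str
    dispersion: float             # gaussian residual mean square; 1 for binomial
    objective_trace: np.ndarray   # phi after init and after every half-step
    converged: bool
    n_iter: int

    def to_json(self, path=None) -> str:
        d = asdict(self)
        for key in ("beta", "weights", "covariate_coefs", "objective_trace"):
            d[key] = np.asarray(d[key]).tolist()
        payload = json.dumps(d, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


# ---------------------------------------------------------------------------
# Likelihood pieces
# ---------------------------------------------------------------------------

def _loglik(eta: np.ndarray, y: np.ndarray, family: str) -> float:
    """Log-likelihood at the linear predictor (gaussian at unit dispersion)."""
    if family == "binomial":
        return float(y @ eta - np.logaddexp(0.0, eta).sum())
    r = y - eta
    return float(-0.5 * (r @ r) - 0.5 * len(y) * _LOG2PI)


def _objective(eta, y, family, w, beta, lambda_g, lambda_p) -> float:
    return (_loglik(eta, y, family)
            - 0.5 * lambda_g * float(w @ w)
            - 0.5 * lambda_p * float(beta @ beta))


def _solve(A: np.ndarray, b: np.ndarray, lam: float) -> np.ndarray:
    try:
        theta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as err:
        if lam == 0:
            raise ValueError(
                "ridge system is singular (exact collinearity); "
                "use a positive penalty"
            ) from err
        raise
    if not np.all(np.isfinite(theta)):
        raise ValueError(
            "ridge system is numerically singular; "
            "use a positive penalty" if lam == 0 else
            "non-finite solution in ridge solve"
        )
    return theta


def ridge_glm_solve(
    X: np.ndarray,
    y: np.ndarray,
    penalty: np.ndarray,
    family: str,
    theta0: np.ndarray | None = None,
    inner_tol: float = 1e-8,
    inner_max: int = 25,
) -> np.ndarray:
    """Maximise ``loglik(y, X theta) - 1/2 sum penalty_i theta_i^2``.

    Closed form for the gaussian family; damped Newton (IRLS with step
    halving on the penalized objective) for the binomial family.  ``penalty``
    is a per-coefficient vector, so intercept/covariate entries can stay
    unpenalised.
    """
    penalty = np.asarray(penalty, dtype=float)
    lam = float(penalty.max(initial=0.0))
    if family == "gaussian":
        A = X.T @ X
        A[np.diag_indices_from(A)] += penalty
        return _solve(A, X.T @ y, lam)
    theta = np.zeros(X.shape[1]) if theta0 is None else np.asarray(theta0, float).copy()

    def obj(t):
        return _loglik(X @ t, y, "binomial") - 0.5 * float(penalty @ (t * t))

    cur = obj(theta)
    for _ in range(inner_max):
        eta = X @ theta
        pi = expit(eta)
        wts = np.clip(pi * (1.0 - pi), 1e-10, None)
        grad = X.T @ (y - pi) - penalty * theta
        H = (X * wts[:, None]).T @ X
        H[np.diag_indices_from(H)] += penalty
        step = _solve(H, grad, lam)
        t_scale = 1.0
        for _ in range(40):
            cand = theta + t_scale * step
            cand_obj = obj(cand)
            if cand_obj >= cur - 1e-12:
                break
            t_scale *= 0.5
        else:
            break  # no ascent possible; stay put
        delta = float(np.max(np.abs(cand - theta)))
        theta, cur = cand, cand_obj
        if delta < inner_tol:
            break
    return theta


# ---------------------------------------------------------------------------
# Initialisation
# ---------------------------------------------------------------------------

def initialize(design: HierarchicalDesign, y: np.ndarray, family: str,
               init: str = "equal", seed: int | None = None) -> dict:
    """Deterministic (or seeded random) starting values for ALS.

    ``equal``: every weight in block k is ``1/sqrt(P_k)`` (unit block norm),
    ``beta = 0``, ``beta0`` the null-model intercept (mean of y, or its
    logit), covariate coefficients 0.  ``random``: weights drawn from a
    seeded standard normal and block-normalised.
    """
    y = np.asarray(y, dtype=float)
    P = design.n_columns
    w = np.empty(P)
    if init == "equal":
        for k in range(design.K):
            cols = design.block_columns(k)
            w[cols] = 1.0 / np.sqrt(len(cols))
    elif init == "random":
        rng = np.random.default_rng(seed)
        w = rng.standard_normal(P)
        for k in range(design.K):
            cols = design.block_columns(k)
            w[cols] /= np.linalg.norm(w[cols])
    else:
        raise ValueError(f"unknown init {init!r}")
    ybar = float(np.mean(y))
    if family == "binomial":
        ybar = min(max(ybar, 1e-10), 1 - 1e-10)
        beta0 = float(np.log(ybar / (1.0 - ybar)))
    else:
        beta0 = ybar
    return {
        "beta0": beta0,
        "beta": np.zeros(design.K),
        "weights": w,
        "covariate_coefs": np.zeros(design.covariates.shape[1]),
    }


# ---------------------------------------------------------------------------
# ALS fit
# ---------------------------------------------------------------------------

def _scores(G, w, blocks):
    S = np.empty((G.shape[0], len(blocks)))
    for k, cols in enumerate(blocks):
        S[:, k] = G[:, cols] @ w[cols]
    return S


def als_fit(
    design: HierarchicalDesign,
    y: np.ndarray,
    family: str = "gaussian",
    lambda_g: float = 1.0,
    lambda_p: float = 1.0,
    init: str = "equal",
    seed: int | None = None,
    init_params: dict | None = None,
    tol: float = 1e-5,
    max_iter: int = 100,
    inner_tol: float = 1e-8,
    inner_max: int = 25,
    warn_on_nonconvergence: bool = True,
) -> HisCoMFit:
    """Fit the hierarchical component GLM by alternating least squares.

    Each outer iteration runs the pathway-coefficient half-step followed by
    the gene-weight half-step; ``objective_trace`` records the penalized
    log-likelihood after initialisation and after every half-step.
    Convergence is declared when the largest absolute parameter change over a
    full iteration, or the objective change, drops below ``tol``.
    """
    cfg = FitConfig(family, lambda_g, lambda_p, tol, max_iter, init, seed)
    y = np.asarray(y, dtype=float)
    G = design.matrix
    Z = design.covariates
    n, P = G.shape
    K, c = design.K, Z.shape[1]
    if len(y) != n:
        raise ValueError("phenotype length does not match design rows")
    blocks = [design.block_columns(k) for k in range(K)]
    bexp_idx = design.col_pathway

    p0 = init_params or initialize(design, y, family, init=init, seed=seed)
    beta0 = float(p0["beta0"])
    beta = np.asarray(p0["beta"], dtype=float).copy()
    w = np.asarray(p0["weights"], dtype=float).copy()
    a = np.asarray(p0["covariate_coefs"], dtype=float).copy()
    ones = np.ones((n, 1))

    gaussian = family == "gaussian"
    if gaussian:
        # cross-products of the fixed frame [1 | G | Z]: the weight half-step
        # design is a column rescaling of this frame, so its normal equations
        # assemble in O(P^2) instead of O(n P^2) per iteration.
        C = np.hstack([ones, G, Z])
        M = C.T @ C
        v = C.T @ y

    def eta_of(beta0_, beta_, w_, a_):
        S = _scores(G, w_, blocks)
        e = beta0_ + S @ beta_
        if c:
            e = e + Z @ a_
        return e

    phi = _objective(eta_of(beta0, beta, w, a), y, family, w, beta,
                     lambda_g, lambda_p)
    trace = [phi]
    if not np.isfinite(phi):
        raise ValueError("non-finite objective at initialisation")

    pen_beta = np.concatenate([[0.0], np.full(K, lambda_p), np.zeros(c)])
    pen_w = np.concatenate([[0.0], np.full(P, lambda_g), np.zeros(c)])
    converged = False
    n_iter = 0
    for it in range(max_iter):
        n_iter = it + 1
        prev = np.concatenate([[beta0], beta, w, a])
        phi_iter = trace[-1]

        # --- half-step 1: pathway coefficients (and intercept, covariates)
        S = _scores(G, w, blocks)
        X1 = np.hstack([ones, S, Z])
        theta0 = np.concatenate([[beta0], beta, a])
        if gaussian:
            A = X1.T @ X1
            A[np.diag_indices_from(A)] += pen_beta
            theta = _solve(A, X1.T @ y, lambda_p)
        else:
            theta = ridge_glm_solve(X1, y, pen_beta, family, theta0,
                                    inner_tol, inner_max)
        beta0, beta, a = float(theta[0]), theta[1:1 + K], theta[1 + K:]
        trace.append(_objective(eta_of(beta0, beta, w, a), y, family,
                                w, beta, lambda_g, lambda_p))

        # --- half-step 2: gene weights (and intercept, covariates)
        bexp = beta[bexp_idx]
        theta0 = np.concatenate([[beta0], w, a])
        if gaussian:
            s = np.concatenate([[1.0], bexp, np.ones(c)])
            A = M * np.outer(s, s)
            A[np.diag_indices_from(A)] += pen_w
            theta = _solve(A, v * s, lambda_g)
        else:
            X2 = np.hstack([ones, G * bexp, Z])
            theta = ridge_glm_solve(X2, y, pen_w, family, theta0,
                                    inner_tol, inner_max)
        beta0, w, a = float(theta[0]), theta[1:1 + P], theta[1 + P:]

        # Exact per-block rescaling w_k <- c w_k, beta_k <- beta_k / c with
        # c minimising the penalty term.  The predictor only sees the product
        # w_k beta_k, so this leaves the likelihood untouched while strictly
        # reducing the penalty — it removes the near-flat scale-split valley
        # that otherwise makes ALS crawl.  Only defined when both penalties
        # are active; at the rebalanced point lambda_g ||w_k||^2 equals
        # lambda_p beta_k^2.
        if lambda_g > 0 and lambda_p > 0:
            for k, cols in enumerate(blocks):
                nw2 = float(w[cols] @ w[cols])
                if nw2 > 0 and beta[k] != 0:
                    cscale = (lambda_p * beta[k] ** 2 / (lambda_g * nw2)) ** 0.25
                    w[cols] *= cscale
                    beta[k] /= cscale
        trace.append(_objective(eta_of(beta0, beta, w, a), y, family,
                                w, beta, lambda_g, lambda_p))

        cur = np.concatenate([[beta0], beta, w, a])
        if (np.max(np.abs(cur - prev)) < tol
                or abs(trace[-1] - phi_iter) < tol):
            converged = True
            break

    if not converged and warn_on_nonconvergence:
        warnings.warn(f"ALS did not converge in {max_iter} iterations")

    # resolve per-block sign indeterminacy: largest-|w| entry positive
    for k, cols in enumerate(blocks):
        wk = w[cols]
        if wk.size and np.any(wk != 0):
            j = int(np.argmax(np.abs(wk)))
            if wk[j] < 0:
                w[cols] = -wk
                beta[k] = -beta[k]

    eta = eta_of(beta0, beta, w, a)
    dispersion = float(np.mean((y - eta) ** 2)) if gaussian else 1.0
    return HisCoMFit(
        beta0=beta0, beta=beta, weights=w, covariate_coefs=a,
        lambda_g=lambda_g, lambda_p=lambda_p, family=family,
        dispersion=dispersion, objective_trace=np.asarray(trace),
        converged=converged, n_iter=n_iter,
    )


# ---------------------------------------------------------------------------
# Derived quantities
# ---------------------------------------------------------------------------

def pathway_scores(design: HierarchicalDesign, weights: np.ndarray) -> np.ndarray:
    """Latent pathway components: column k is ``sum_{t,i} g_kti w_kti``."""
    blocks = [design.block_columns(k) for k in range(design.K)]
    return _scores(design.matrix, np.asarray(weights, float), blocks)


def linear_predictor(design: HierarchicalDesign, fit: HisCoMFit) -> np.ndarray:
    """``eta`` for every sample; the GLM mean is ``expit(eta)`` (binomial)
    or ``eta`` itself (gaussian)."""
    if len(fit.beta) != design.K or len(fit.weights) != design.n_columns:
        raise ValueError("fit dimensions do not match design")
    if len(fit.covariate_coefs) != design.covariates.shape[1]:
        raise ValueError("covariate coefficient length does not match design")
    eta = fit.beta0 + pathway_scores(design, fit.weights) @ fit.beta
    if design.covariates.shape[1]:
        eta = eta + design.covariates @ fit.covariate_coefs
    return eta


def penalized_loglik(design: HierarchicalDesign, fit: HisCoMFit,
                     y: np.ndarray) -> float:
    """Penalized log-likelihood ``phi`` of a fit on data ``y``.

    Unlike the optimisation trace (which uses unit dispersion), the gaussian
    likelihood here is evaluated at the fit's stored ``dispersion``.
    Penalties apply to the gene weights and pathway coefficients only —
    never to the intercept or covariate coefficients.
    """
    y = np.asarray(y, dtype=float)
    eta = linear_predictor(design, fit)
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite linear predictor")
    if fit.family == "binomial":
        ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
    else:
        if fit.dispersion <= 0:
            raise ValueError("gaussian dispersion must be positive")
        r = y - eta
        ll = float(-0.5 * (r @ r) / fit.dispersion
                   - 0.5 * len(y) * (_LOG2PI + np.log(fit.dispersion)))
    return (ll - 0.5 * fit.lambda_g * float(fit.weights @ fit.weights)
            - 0.5 * fit.lambda_p * float(fit.beta @ fit.beta))
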