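"""Penalty selection by k-fold cross-validation.

The two ridge parameters (gene-weight penalty ``lambda_g`` and pathway
penalty ``lambda_p``) are chosen over a grid by out-of-fold predictive loss,
defined as half the deviance (the held-out negative log-likelihood at unit
dispersion), which treats the gaussian and binomial families uniformly.
Folds are a seeded shuffle, stratified by outcome for binomial traits, and
ties in mean loss are broken conservatively toward the heavier penalty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .core import als_fit, pathway_scores
from .genepc import HierarchicalDesign

__all__ = ["CVResult", "cv_select"]

# default log-spaced grid spanning under- to over-penalisation
DEFAULT_GRID = (0.01, 0.1, 1.0, 10.0, 100.0, 1000.0)


@dataclass
class CVResult:
    grid: list[tuple[float, float]]       # (lambda_g, lambda_p) pairs
    fold_losses: np.ndarray               # (len(grid), k)
    fold_sizes: np.ndarray                # (k,)
    mean_losses: np.ndarray               # fold-size weighted
    best: tuple[float, float]
    k: int
    seed: int | None

    def to_dict(self) -> dict:
        return {
            "grid": [list(g) for g in self.grid],
            "fold_losses": self.fold_losses.tolist(),
            "fold_sizes": self.fold_sizes.tolist(),
            "mean_losses": self.mean_losses.tolist(),
            "best": list(self.best),
            "k": self.k,
            "seed": self.seed,
        }


def _heldout_loss(design, fit, y, idx, family):
    """Half-deviance of the fit on held-out rows ``idx``."""
    S = pathway_scores(design, fit.weights)[idx]
    eta = fit.beta0 + S @ fit.beta
    if design.covariates.shape[1]:
        eta = eta + design.covariates[idx] @ fit.covariate_coefs
    yy = y[idx]
    if family == "binomial":
        return float(np.logaddexp(0.0, eta).sum() - yy @ eta)
    r = yy - eta
    return float(0.5 * (r @ r))


def cv_select(
    design: HierarchicalDesign,
    y: np.ndarray,
    family: str = "gaussian",
    grid_g=DEFAULT_GRID,
    grid_p=DEFAULT_GRID,
    k: int = 5,
    seed: int | None = None,
    tol: float = 1e-5,
    max_iter: int = 100,
) -> CVResult:
    """Select ``(lambda_g, lambda_p)`` by k-fold cross-validated loss.

    Each grid pair is fitted on k-1 folds and scored on the held-out fold;
    losses are combined with fold-size weights.  The best pair attains the
    minimal mean loss; exact ties go to the larger ``lambda_g + lambda_p``,
    then the larger ``lambda_p``.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError("need at least k samples")
    grid_g, grid_p = list(grid_g), list(grid_p)
    if not grid_g or not grid_p:
        raise ValueError("penalty grids must be non-empty")

    if family == "binomial":
        classes, counts = np.unique(y, return_counts=True)
        if counts.min() < k:
            raise ValueError(
                "cannot build stratified folds: a class has fewer samples "
                "than folds"
            )
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = list(splitter.split(np.zeros(n), y.astype(int)))
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        splits = list(splitter.split(np.zeros(n)))

    grid = [(lg, lp) for lg in grid_g for lp in grid_p]
    fold_losses = np.empty((len(grid), k))
    fold_sizes = np.array([len(test) for _, test in splits])
    for gi, (lg, lp) in enumerate(grid):
        for fi, (train, test) in enumerate(splits):
            fit = als_fit(
                design.subset_rows(train), y[train], family=family,
                lambda_g=lg, lambda_p=lp, tol=tol, max_iter=max_iter,
                warn_on_nonconvergence=False,
            )
            fold_losses[gi, fi] = _heldout_loss(design, fit, y, test, family)
    if not np.all(np.isfinite(fold_losses)):
        raise ValueError("non-finite cross-validation loss")
    mean_losses = fold_losses @ fold_sizes / fold_sizes.sum()

    best_i = 0
    for i in range(1, len(grid)):
        cur, best = mean_losses[i], mean_losses[best_i]
        if cur < best - 1e-12:
            best_i = i
        elif abs(cur - best) <= 1e-12:
            lg_i, lp_i = grid[i]
            lg_b, lp_b = grid[best_i]
            if (lg_i + lp_i, lp_i) > (lg_b + lp_b, lp_b):
                best_i = i
    return CVResult(
        grid=grid, fold_losses=fold_losses, fold_sizes=fold_sizes,
        mean_losses=mean_losses, best=grid[best_i], k=k, seed=seed,
    )
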