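"""Permutation inference for pathway and gene effects, plus BH-FDR.

Significance is assessed by resampling the phenotype: the model is refitted
from scratch (same configuration, deterministic initialisation) on each
permuted phenotype vector, covariate rows staying put, and the observed
statistic is ranked within the permutation null.  The pathway statistic is
``|beta_k|``; the gene statistic is ``max_i |w_kti * beta_k|`` over that
gene's PC columns within its pathway.  p-values use the add-one estimator
``(1 + #{permuted >= observed}) / (B + 1)``, which is strictly positive and
valid.  Benjamini-Hochberg q-values are attached per table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .core import FitConfig, als_fit
from .genepc import HierarchicalDesign

__all__ = ["PermutationResult", "permutation_test", "bh_fdr",
           "significant_pathways"]


@dataclass
class PermutationResult:
    """Observed statistics, permutation counts and p/q-values."""

    pathway_ids: list[str]
    coefficients: np.ndarray      # signed beta_k from the observed fit
    observed: np.ndarray          # |beta_k|
    counts: np.ndarray            # #{b : |beta_k^(b)| >= |beta_k|}
    B: int                        # permutations attempted
    n_failed: int                 # permuted refits that failed to converge
    p_values: np.ndarray
    q_values: np.ndarray
    gene_table: pd.DataFrame | None
    seed: int | None

    def pathway_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "pathway_id": self.pathway_ids,
            "coefficient": self.coefficients,
            "p_value": self.p_values,
            "q_value": self.q_values,
        })


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg q-values (monotone, capped at 1, input order)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _gene_stats(design: HierarchicalDesign, fit) -> np.ndarray:
    """Per (pathway, gene) statistic: max |w * beta_k| over the gene's PCs,
    in design column order."""
    groups = design.gene_groups()
    out = np.empty(len(groups))
    for g_i, (k, _gene, cols) in enumerate(groups):
        out[g_i] = np.max(np.abs(fit.weights[cols] * fit.beta[k]))
    return out


def _gene_coefs(design: HierarchicalDesign, fit) -> np.ndarray:
    """Signed ``w * beta`` of the max-|.| PC per (pathway, gene)."""
    groups = design.gene_groups()
    out = np.empty(len(groups))
    for g_i, (k, _gene, cols) in enumerate(groups):
        vals = fit.weights[cols] * fit.beta[k]
        out[g_i] = vals[int(np.argmax(np.abs(vals)))]
    return out


def permutation_test(
    design: HierarchicalDesign,
    y: np.ndarray,
    fit_config: FitConfig,
    B: int = 1000,
    seed: int | None = None,
    permutations=None,
    method: str = "phenotype",
    compute_gene_level: bool = True,
    max_failure_rate: float = 0.05,
) -> PermutationResult:
    """Permutation test of all pathway (and gene) effects in one joint model.

    Parameters
    ----------
    fit_config
        Fully specifies the refit (family, penalties, tolerance, init); the
        same configuration is used for the observed fit and every permuted
        refit, with weights re-estimated from scratch each time.
    B, seed
        Number of uniform random phenotype permutations and the RNG seed.
    permutations
        Optional explicit iterable of index arrays overriding the random
        permutations (used for exhaustive or diagnostic permutation sets).
    method
        ``"phenotype"`` permutes the phenotype vector directly;
        ``"freedman_lane"`` (gaussian only) permutes residuals from the
        covariate-only model and adds them back to its fitted values, for
        covariate-confounded designs.

    Permuted refits that fail to converge are counted, excluded from the
    null, and a failure fraction above ``max_failure_rate`` raises.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    y = np.asarray(y, dtype=float)
    n = len(y)

    def fit_on(yy):
        return als_fit(
            design, yy, family=fit_config.family,
            lambda_g=fit_config.lambda_g, lambda_p=fit_config.lambda_p,
            init=fit_config.init, seed=fit_config.seed,
            tol=fit_config.tol, max_iter=fit_config.max_iter,
            warn_on_nonconvergence=False,
        )

    obs_fit = fit_on(y)
    obs_stat = np.abs(obs_fit.beta)
    obs_gene = _gene_stats(design, obs_fit) if compute_gene_level else None

    if method == "freedman_lane":
        if fit_config.family != "gaussian":
            raise ValueError("freedman_lane permutation requires the gaussian family")
        Zc = np.hstack([np.ones((n, 1)), design.covariates])
        coef, *_ = np.linalg.lstsq(Zc, y, rcond=None)
        fitted = Zc @ coef
        resid = y - fitted
    elif method != "phenotype":
        raise ValueError(f"unknown permutation method {method!r}")

    if permutations is None:
        rng = np.random.default_rng(seed)
        permutations = (rng.permutation(n) for _ in range(B))
        n_perm = B
    else:
        permutations = list(permutations)
        n_perm = len(permutations)

    counts = np.zeros(design.K)
    gene_counts = np.zeros(len(obs_gene)) if obs_gene is not None else None
    n_failed = 0
    n_done = 0
    for perm in permutations:
        y_b = (fitted + resid[perm]) if method == "freedman_lane" else y[perm]
        fit_b = fit_on(y_b)
        if not fit_b.converged:
            n_failed += 1
            continue
        n_done += 1
        counts += np.abs(fit_b.beta) >= obs_stat
        if gene_counts is not None:
            gene_counts += _gene_stats(design, fit_b) >= obs_gene
    if n_failed > max_failure_rate * n_perm:
        raise RuntimeError(
            f"{n_failed}/{n_perm} permuted refits failed to converge"
        )

    p = (1.0 + counts) / (n_done + 1.0)
    q = bh_fdr(p)
    gene_table = None
    if obs_gene is not None:
        groups = design.gene_groups()
        gene_p = (1.0 + gene_counts) / (n_done + 1.0)
        gene_table = pd.DataFrame({
            "pathway_id": [design.pathway_ids[k] for k, _, _ in groups],
            "gene": [g for _, g, _ in groups],
            "coefficient": _gene_coefs(design, obs_fit),
            "p_value": gene_p,
            "q_value": bh_fdr(gene_p),
        })
    return PermutationResult(
        pathway_ids=list(design.pathway_ids),
        coefficients=obs_fit.beta.copy(),
        observed=obs_stat, counts=counts.astype(int), B=n_perm,
        n_failed=n_failed, p_values=p, q_values=q,
        gene_table=gene_table, seed=seed,
    )


def significant_pathways(result: PermutationResult, alpha: float = 0.05,
                         corrected: bool = False) -> list[str]:
    """Pathways with p < alpha (nominal) or q < alpha (FDR-corrected),
    preserving input order."""
    vals = result.q_values if corrected else result.p_values
    return [pid for pid, v in zip(result.pathway_ids, vals) if v < alpha]
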