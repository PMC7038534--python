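"""Shared fixtures: random hierarchical designs, tiny simulated datasets and
a pool of Monte-Carlo null p-values reused by the calibration tests."""

import numpy as np
import pandas as pd
import pytest

from hiscom_pca import (
    FitConfig,
    GenotypeMatrix,
    HierarchicalDesign,
    permutation_test,
)


def make_random_design(seed, n=60, K=3, genes_per_block=2, pcs_per_gene=1,
                       n_covariates=0):
    """A hierarchical design with independent standard-normal PC columns."""
    rng = np.random.default_rng(seed)
    cols, col_pathway, col_gene, col_pc = [], [], [], []
    for k in range(K):
        for t in range(genes_per_block):
            for i in range(pcs_per_gene):
                x = rng.standard_normal(n)
                cols.append(x - x.mean())
                col_pathway.append(k)
                col_gene.append(f"P{k}G{t}")
                col_pc.append(i)
    Z = rng.standard_normal((n, n_covariates))
    return HierarchicalDesign(
        matrix=np.column_stack(cols),
        col_pathway=np.array(col_pathway),
        col_gene=col_gene,
        col_pc=np.array(col_pc),
        pathway_ids=[f"PW{k}" for k in range(K)],
        covariates=Z,
        covariate_names=[f"cov{i}" for i in range(n_covariates)],
    )


@pytest.fixture
def random_design():
    return make_random_design


def make_genotypes(dosages, chrom="1", start_pos=100):
    """Wrap a plain dosage array in a GenotypeMatrix with stub metadata."""
    dosages = np.asarray(dosages, dtype=float)
    n, p = dosages.shape
    meta = pd.DataFrame({
        "snp_id": [f"rs{j}" for j in range(p)],
        "chrom": [chrom] * p,
        "pos": start_pos + 10 * np.arange(p),
        "allele_ref": ["A"] * p,
        "allele_alt": ["B"] * p,
    })
    return GenotypeMatrix(dosages, meta, [f"S{i}" for i in range(n)])


@pytest.fixture
def genotypes_factory():
    return make_genotypes


@pytest.fixture(scope="session")
def null_pvalues():
    """500 Monte-Carlo p-values of one tracked pathway under a global null.

    Gaussian phenotype independent of a small 3-pathway design, B=99
    permutations each; used by both the rejection-rate and the
    distribution-uniformity calibration tests.
    """
    design = make_random_design(seed=202, n=60, K=3)
    rng = np.random.default_rng(915)
    fc = FitConfig(family="gaussian", lambda_g=1.0, lambda_p=1.0)
    pvals = np.empty(500)
    for r in range(500):
        y = rng.standard_normal(design.n_samples)
        res = permutation_test(design, y, fc, B=99,
                               seed=int(rng.integers(2 ** 31)),
                               compute_gene_level=False)
        pvals[r] = res.p_values[0]
    return pvals
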