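"""SNP-to-gene mapping, per-gene PCA and hierarchical design assembly.

Step 1 of the pathway model: SNPs are assigned to genes when they fall inside
the gene body or within a flanking window (20 kb by default), each gene's
dosage submatrix is reduced by PCA, and a small number of leading components
is retained per gene — either just the first PC, or the minimal leading set
whose cumulative variance proportion exceeds 30%.  The selected PC score
columns, grouped pathway-by-pathway, form the design of the hierarchical
model fitted in :mod:`hiscom_pca.core`.

PC signs are fixed deterministically (the largest-magnitude loading in each
component is made positive) so repeated runs and permutation refits see
bit-identical inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats import GeneAnnotation, GenotypeMatrix, PathwayDB

__all__ = [
    "SnpGeneMap",
    "GenePCA",
    "GenePCSet",
    "HierarchicalDesign",
    "map_snps_to_genes",
    "gene_pca",
    "select_pcs",
    "compute_gene_pcs",
    "build_design",
]


@dataclass
class SnpGeneMap:
    """SNP -> gene assignments; one SNP may map to several genes."""

    assignments: list[tuple[str, str]]  # (snp_id, gene)
    window_bp: int
    n_unmapped: int = 0

    def genes(self) -> list[str]:
        """Mapped genes in order of first appearance."""
        return list(dict.fromkeys(g for _, g in self.assignments))

    def snps_of_gene(self, gene: str) -> list[str]:
        return [s for s, g in self.assignments if g == gene]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.assignments, columns=["snp_id", "gene"])


def map_snps_to_genes(snp_meta: pd.DataFrame, annotation: GeneAnnotation,
                      window_bp: int = 20000) -> SnpGeneMap:
    """Assign SNPs to genes within ``window_bp`` of the gene body.

    SNP ``s`` maps to gene ``g`` iff chromosomes match and
    ``start - window_bp <= pos <= end + window_bp`` (both bounds inclusive).
    SNPs mapping to no gene are counted but otherwise ignored.
    """
    if len(annotation) == 0:
        raise ValueError("gene annotation is empty")
    assignments: list[tuple[str, str]] = []
    mapped = np.zeros(len(snp_meta), dtype=bool)
    pos = snp_meta["pos"].to_numpy()
    chrom = snp_meta["chrom"].to_numpy()
    ids = snp_meta["snp_id"].to_numpy()
    for rec in annotation.records.itertuples(index=False):
        mask = (chrom == rec.chrom) & (pos >= rec.start - window_bp) \
            & (pos <= rec.end + window_bp)
        idx = np.flatnonzero(mask)
        assignments.extend((ids[i], rec.gene) for i in idx)
        mapped[idx] = True
    return SnpGeneMap(assignments, window_bp, n_unmapped=int((~mapped).sum()))


@dataclass
class GenePCA:
    """PCA summary of one gene's SNPs."""

    gene: str
    snp_ids: list[str]          # SNPs actually entering the PCA (non-constant)
    scores: np.ndarray          # (n_samples, n_pcs), column-centred
    loadings: np.ndarray        # (len(snp_ids), n_pcs)
    variance_proportions: np.ndarray  # descending, sums to ~1
    n_selected: int = 1


@dataclass
class GenePCSet:
    """Per-gene PCA results plus genes dropped for having no variation."""

    entries: dict[str, GenePCA] = field(default_factory=dict)
    dropped_genes: list[str] = field(default_factory=list)

    def __contains__(self, gene: str) -> bool:
        return gene in self.entries

    def __getitem__(self, gene: str) -> GenePCA:
        return self.entries[gene]

    def total_selected(self) -> int:
        return sum(e.n_selected for e in self.entries.values())


def gene_pca(X: np.ndarray, scale: bool = True):
    """PCA of one gene's dosage submatrix via SVD.

    Columns are centred and (by default) scaled to unit variance, so the
    decomposition matches an eigendecomposition of the SNP correlation
    matrix.  Constant columns are dropped beforehand; if every column is
    constant a ``ValueError`` is raised (the caller drops the gene).

    Returns ``(scores, loadings, variance_proportions, kept_cols)`` where
    ``kept_cols`` indexes the non-constant input columns.  Component signs
    follow the largest-|loading|-positive convention, which makes the result
    deterministic.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("gene submatrix must be 2-D with >= 1 SNP")
    if np.isnan(X).any():
        raise ValueError("gene submatrix contains missing values; impute first")
    sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    kept = np.flatnonzero(sd > 0)
    if kept.size == 0:
        raise ValueError("all SNP columns are constant")
    if kept.size < X.shape[1]:
        warnings.warn(f"dropping {X.shape[1] - kept.size} constant SNP column(s)")
    Xc = X[:, kept] - X[:, kept].mean(axis=0)
    if scale:
        Xc = Xc / sd[kept]
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float(np.sum(s ** 2))
    r = max(1, int(np.sum(s > s[0] * 1e-9)))
    scores = U[:, :r] * s[:r]
    loadings = Vt[:r].T
    varprop = s[:r] ** 2 / total
    # deterministic sign: largest-|loading| entry positive per component
    for m in range(r):
        j = int(np.argmax(np.abs(loadings[:, m])))
        if loadings[j, m] < 0:
            loadings[:, m] *= -1
            scores[:, m] *= -1
    return scores, loadings, varprop, kept


def select_pcs(variance_proportions: np.ndarray, criterion: str = "first_pc",
               cumvar_threshold: float = 0.30) -> int:
    """Number of leading PCs to retain for one gene.

    ``first_pc`` always returns 1; ``cumvar`` returns the smallest m whose
    cumulative variance proportion is strictly greater than the threshold.
    """
    vp = np.asarray(variance_proportions, dtype=float)
    if vp.size == 0:
        raise ValueError("no principal components to select from")
    if criterion == "first_pc":
        return 1
    if criterion == "cumvar":
        cum = np.cumsum(vp)
        hit = np.flatnonzero(cum > cumvar_threshold)
        return int(hit[0]) + 1 if hit.size else vp.size
    raise ValueError(f"unknown PC selection criterion {criterion!r}")


def compute_gene_pcs(
    G: GenotypeMatrix,
    mapping: SnpGeneMap,
    criterion: str = "first_pc",
    cumvar_threshold: float = 0.30,
    scale: bool = True,
) -> GenePCSet:
    """Run :func:`gene_pca` + :func:`select_pcs` for every mapped gene."""
    col_of = {sid: j for j, sid in enumerate(G.snp_meta["snp_id"])}
    out = GenePCSet()
    for gene in mapping.genes():
        snps = [s for s in mapping.snps_of_gene(gene) if s in col_of]
        if not snps:
            out.dropped_genes.append(gene)
            continue
        cols = [col_of[s] for s in snps]
        try:
            scores, loadings, varprop, kept = gene_pca(G.dosages[:, cols], scale=scale)
        except ValueError:
            warnings.warn(f"gene {gene!r} dropped: no SNP variation")
            out.dropped_genes.append(gene)
            continue
        n_sel = select_pcs(varprop, criterion, cumvar_threshold)
        out.entries[gene] = GenePCA(
            gene=gene, snp_ids=[snps[i] for i in kept], scores=scores,
            loadings=loadings, variance_proportions=varprop, n_selected=n_sel,
        )
    return out


@dataclass
class HierarchicalDesign:
    """Pathway -> gene -> PC block structure flattened to a design matrix.

    ``matrix`` holds every selected PC score column; ``col_pathway[j]`` gives
    the pathway (block) index of column ``j``, ``col_gene[j]`` its gene and
    ``col_pc[j]`` the PC number within the gene (0-based).  A gene shared by
    several pathways contributes numerically identical columns to each of its
    pathway blocks, each with its own weight in the model.  Covariates ride
    along unpenalised.
    """

    matrix: np.ndarray
    col_pathway: np.ndarray
    col_gene: list[str]
    col_pc: np.ndarray
    pathway_ids: list[str]
    covariates: np.ndarray
    covariate_names: list[str]
    dropped_pathways: list[str] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    @property
    def K(self) -> int:
        return len(self.pathway_ids)

    def block_columns(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.col_pathway == k)

    def gene_groups(self) -> list[tuple[int, str, np.ndarray]]:
        """(pathway index, gene, column indices) in design column order."""
        seen: dict[tuple[int, str], list[int]] = {}
        for j, (k, g) in enumerate(zip(self.col_pathway, self.col_gene)):
            seen.setdefault((int(k), g), []).append(j)
        return [(k, g, np.array(cols)) for (k, g), cols in seen.items()]

    def subset_rows(self, idx) -> "HierarchicalDesign":
        idx = np.asarray(idx)
        return HierarchicalDesign(
            self.matrix[idx], self.col_pathway, self.col_gene, self.col_pc,
            self.pathway_ids, self.covariates[idx], self.covariate_names,
            self.dropped_pathways,
        )

    def summary(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "n_pathways": self.K,
            "n_gene_blocks": len(self.gene_groups()),
            "n_pc_columns": self.n_columns,
            "n_covariates": self.covariates.shape[1],
            "dropped_pathways": list(self.dropped_pathways),
        }


def build_design(
    pc_set: GenePCSet,
    pathways: PathwayDB,
    covariates: np.ndarray | None = None,
    covariate_names: list[str] | None = None,
) -> HierarchicalDesign:
    """Assemble the hierarchical design from per-gene PCs and gene sets.

    Pathways whose genes all lack PCs are dropped (and recorded).  With the
    ``first_pc`` criterion the total number of columns equals the number of
    mapped (pathway, gene) pairs.
    """
    cols: list[np.ndarray] = []
    col_pathway: list[int] = []
    col_gene: list[str] = []
    col_pc: list[int] = []
    pathway_ids: list[str] = []
    dropped: list[str] = []
    for pw in pathways:
        genes = [g for g in pw.genes if g in pc_set]
        if not genes:
            dropped.append(pw.pathway_id)
            continue
        k = len(pathway_ids)
        pathway_ids.append(pw.pathway_id)
        for g in genes:
            entry = pc_set[g]
            m = entry.n_selected
            cols.append(entry.scores[:, :m])
            col_pathway.extend([k] * m)
            col_gene.extend([g] * m)
            col_pc.extend(range(m))
    if not pathway_ids:
        raise ValueError("empty design: no pathway retains a gene with PCs")
    matrix = np.hstack(cols)
    n = matrix.shape[0]
    if covariates is None:
        covariates = np.empty((n, 0))
        covariate_names = []
    covariates = np.asarray(covariates, dtype=float).reshape(n, -1)
    if covariate_names is None:
        covariate_names = [f"cov{i}" for i in range(covariates.shape[1])]
    return HierarchicalDesign(
        matrix=matrix,
        col_pathway=np.asarray(col_pathway),
        col_gene=col_gene,
        col_pc=np.asarray(col_pc),
        pathway_ids=pathway_ids,
        covariates=covariates,
        covariate_names=list(covariate_names),
        dropped_pathways=dropped,
    )
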