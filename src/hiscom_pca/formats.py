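"""File formats and domain containers for the pathway-association pipeline.

This module owns the in-memory types the rest of the package operates on
(:class:`GenotypeMatrix`, :class:`PhenotypeData`, :class:`PathwayDB`,
:class:`GeneAnnotation`) and the readers/writers for the standard text and
binary formats they come from: PLINK-1 binary genotype trios (BED/BIM/FAM),
GMT gene-set files, tab-separated phenotype/covariate tables and the results
table written at the end of an analysis.

Conventions
-----------
* Dosages are stored as ``float64`` counts of the *counted* allele, with
  ``numpy.nan`` as the missing sentinel (0 is a valid dosage, so missing must
  be out of band).  For PLINK input the counted allele is BIM A1, following
  PLINK's own convention.
* All containers preserve input order (SNPs, samples, pathways), so every
  downstream artifact is deterministically ordered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ConsistencyError",
    "GenotypeMatrix",
    "PhenotypeData",
    "Pathway",
    "PathwayDB",
    "GeneAnnotation",
    "read_plink",
    "write_plink",
    "read_gmt",
    "write_gmt",
    "read_gene_annotation",
    "read_phenotype_table",
    "align_samples",
    "write_results",
]

_PLINK_MAGIC = b"\x6c\x1b"
_SNP_MAJOR = b"\x01"

# 2-bit PLINK genotype codes -> dosage of the A1 (counted) allele.
# 00 = hom A1 (2 copies), 01 = missing, 10 = het, 11 = hom A2.
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ConsistencyError(ValueError):
    """Mutually inconsistent companion files (e.g. BED/BIM/FAM counts)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Samples x SNPs dosage matrix with per-SNP metadata.

    Parameters
    ----------
    dosages
        ``(n_samples, n_snps)`` float array; non-missing entries are in
        ``{0, 1, 2}`` before imputation (continuous values are allowed after
        mean imputation).  Missing entries are ``nan``.
    snp_meta
        DataFrame with columns ``snp_id``, ``chrom``, ``pos`` (1-based bp),
        ``allele_ref``, ``allele_alt``; ``allele_alt`` is the counted allele.
    sample_ids
        Unique sample identifiers, one per row of ``dosages``.
    sample_sex
        Optional per-sample sex code (PLINK: 1 male, 2 female, 0 unknown).
    """

    dosages: np.ndarray
    snp_meta: pd.DataFrame
    sample_ids: list[str]
    sample_sex: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D samples x SNPs array")
        if len(self.snp_meta) != self.dosages.shape[1]:
            raise ConsistencyError(
                f"snp_meta has {len(self.snp_meta)} rows but dosages has "
                f"{self.dosages.shape[1]} SNP columns"
            )
        if len(self.sample_ids) != self.dosages.shape[0]:
            raise ConsistencyError(
                f"{len(self.sample_ids)} sample ids for "
                f"{self.dosages.shape[0]} dosage rows"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ConsistencyError("sample ids are not unique")
        if (self.snp_meta["pos"] < 1).any():
            raise ValueError("SNP positions must be 1-based (>= 1)")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def validate_dosage_values(self) -> None:
        """Check that every non-missing dosage is 0, 1 or 2."""
        vals = self.dosages[~np.isnan(self.dosages)]
        if not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("non-missing dosages must be in {0, 1, 2}")

    def subset(self, sample_idx=None, snp_idx=None) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given sample/SNP indices."""
        d = self.dosages
        ids = self.sample_ids
        sex = self.sample_sex
        meta = self.snp_meta
        if sample_idx is not None:
            sample_idx = np.asarray(sample_idx)
            d = d[sample_idx]
            ids = [self.sample_ids[i] for i in sample_idx]
            sex = sex[sample_idx] if sex is not None else None
        if snp_idx is not None:
            snp_idx = np.asarray(snp_idx)
            d = d[:, snp_idx]
            meta = meta.iloc[snp_idx].reset_index(drop=True)
        return GenotypeMatrix(d.copy(), meta.copy(), list(ids),
                              None if sex is None else np.asarray(sex).copy())


@dataclass
class PhenotypeData:
    """Aligned phenotype vector plus covariates for one analysis.

    ``family`` is ``"gaussian"`` for continuous traits and ``"binomial"`` for
    case/control traits coded 0/1.
    """

    y: np.ndarray
    family: str
    covariates: np.ndarray
    covariate_names: list[str]
    sample_ids: list[str]
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.covariates = np.asarray(self.covariates, dtype=float)
        if self.covariates.ndim == 1:
            self.covariates = self.covariates.reshape(len(self.y), -1)
        if self.family not in ("gaussian", "binomial"):
            raise ValueError(f"unknown family {self.family!r}")
        if np.isnan(self.y).any():
            raise ValueError("phenotype contains missing values after alignment")
        if self.family == "binomial" and not np.isin(self.y, (0.0, 1.0)).all():
            raise ValueError("binomial phenotype must be coded {0, 1}")
        if self.covariates.shape[0] != len(self.y):
            raise ConsistencyError("covariate rows do not align with phenotype")

    def subset(self, idx) -> "PhenotypeData":
        idx = np.asarray(idx)
        return PhenotypeData(
            self.y[idx], self.family, self.covariates[idx],
            list(self.covariate_names), [self.sample_ids[i] for i in idx],
            self.n_dropped,
        )


@dataclass(frozen=True)
class Pathway:
    pathway_id: str
    description: str
    genes: tuple[str, ...]  # deduplicated, input order preserved


@dataclass
class PathwayDB:
    """Ordered collection of gene sets (e.g. KEGG pathways)."""

    pathways: dict[str, Pathway] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways.values())

    def gene_set(self, pathway_id: str) -> set[str]:
        return set(self.pathways[pathway_id].genes)

    def add(self, pathway: Pathway) -> None:
        if pathway.pathway_id in self.pathways:
            raise ConsistencyError(f"duplicate pathway id {pathway.pathway_id!r}")
        if not pathway.genes:
            raise ValueError(f"pathway {pathway.pathway_id!r} has an empty gene set")
        self.pathways[pathway.pathway_id] = pathway


@dataclass
class GeneAnnotation:
    """Gene intervals: ``gene``, ``chrom``, ``start``, ``end`` (1-based, inclusive)."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene", "chrom", "start", "end"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"annotation missing columns: {sorted(missing)}")
        if (self.records["start"] > self.records["end"]).any():
            raise ValueError("gene annotation has start > end")
        dup = self.records.duplicated(subset=["gene", "chrom"])
        if dup.any():
            raise ValueError("gene symbols must be unique per chromosome")

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# PLINK binary trio
# ---------------------------------------------------------------------------

def read_plink(bed_path, bim_path, fam_path) -> GenotypeMatrix:
    """Read a PLINK-1 binary trio into a :class:`GenotypeMatrix`.

    The BED file must be in SNP-major order (the PLINK 1 default).  Dosages
    count copies of the BIM A1 allele; the PLINK missing code maps to ``nan``.

    Raises
    ------
    FormatError
        If the BED magic bytes or mode byte are wrong.
    ConsistencyError
        If the BED payload size disagrees with the BIM/FAM row counts.
    """
    bim = pd.read_csv(
        bim_path, sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp_id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        fam_path, sep=r"\s+", header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    n_snps, n_samples = len(bim), len(fam)
    raw = Path(bed_path).read_bytes()
    if raw[:2] != _PLINK_MAGIC:
        raise FormatError(f"{bed_path}: not a PLINK .bed file (bad magic bytes)")
    if raw[2:3] != _SNP_MAJOR:
        raise FormatError(f"{bed_path}: only SNP-major .bed files are supported")
    bytes_per_snp = (n_samples + 3) // 4
    expected = 3 + n_snps * bytes_per_snp
    if len(raw) != expected:
        raise ConsistencyError(
            f"{bed_path}: payload is {len(raw) - 3} bytes but BIM/FAM imply "
            f"{expected - 3} ({n_snps} SNPs x {bytes_per_snp} bytes)"
        )
    data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(n_snps, bytes_per_snp)
    j = np.arange(n_samples)
    codes = (data[:, j // 4] >> (2 * (j % 4)).astype(np.uint8)) & 3
    dosages = _CODE_TO_DOSAGE[codes].T  # (n_samples, n_snps)

    meta = pd.DataFrame({
        "snp_id": bim["snp_id"],
        "chrom": bim["chrom"],
        "pos": bim["pos"].astype(int),
        "allele_ref": bim["a2"],
        "allele_alt": bim["a1"],
    })
    return GenotypeMatrix(dosages, meta, list(fam["iid"]),
                          fam["sex"].to_numpy())


def write_plink(G: GenotypeMatrix, prefix) -> None:
    """Write ``prefix``.bed/.bim/.fam (SNP-major PLINK-1)."""
    G.validate_dosage_values()
    prefix = Path(prefix)
    n, p = G.dosages.shape
    # dosage -> 2-bit code: 2 -> 00, missing -> 01, 1 -> 10, 0 -> 11
    codes = np.full((p, n), 1, dtype=np.uint8)
    d = G.dosages.T
    codes[d == 2.0] = 0
    codes[d == 1.0] = 2
    codes[d == 0.0] = 3
    bytes_per_snp = (n + 3) // 4
    padded = np.zeros((p, bytes_per_snp * 4), dtype=np.uint8)
    padded[:, :n] = codes
    shifts = (2 * (np.arange(4))).astype(np.uint8)
    packed = (padded.reshape(p, bytes_per_snp, 4) << shifts).sum(axis=2).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_PLINK_MAGIC + _SNP_MAJOR)
        fh.write(packed.tobytes())

    bim = pd.DataFrame({
        "chrom": G.snp_meta["chrom"],
        "snp_id": G.snp_meta["snp_id"],
        "cm": 0,
        "pos": G.snp_meta["pos"],
        "a1": G.snp_meta["allele_alt"],
        "a2": G.snp_meta["allele_ref"],
    })
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    sex = G.sample_sex if G.sample_sex is not None else np.zeros(n, dtype=int)
    fam = pd.DataFrame({
        "fid": G.sample_ids, "iid": G.sample_ids, "pat": 0, "mat": 0,
        "sex": np.asarray(sex, dtype=int), "pheno": -9,
    })
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path) -> PathwayDB:
    """Read a tab-separated GMT file (id, description, member genes...).

    Pathway order follows the file; genes repeated on one line are
    deduplicated (first occurrence wins).  A non-empty line with fewer than
    three fields is a :class:`FormatError` naming the offending line.
    """
    db = PathwayDB()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: GMT lines need id, description "
                    f"and at least one gene ({len(fields)} fields found)"
                )
            genes = tuple(dict.fromkeys(g for g in fields[2:] if g))
            if not genes:
                raise FormatError(f"{path}: line {lineno}: empty gene set")
            db.add(Pathway(fields[0], fields[1], genes))
    if len(db) == 0:
        warnings.warn(f"{path}: GMT file contains no pathways")
    return db


def write_gmt(db: PathwayDB, path) -> None:
    with open(path, "w") as fh:
        for pw in db:
            fh.write("\t".join((pw.pathway_id, pw.description) + pw.genes) + "\n")


def read_gene_annotation(path) -> GeneAnnotation:
    """Read a 4-column TSV (gene, chrom, start, end; 1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str})
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return GeneAnnotation(df)


# ---------------------------------------------------------------------------
# Phenotype / covariate tables
# ---------------------------------------------------------------------------

def read_phenotype_table(
    path,
    pheno_col: str,
    covar_cols: Sequence[str] = (),
    family: str = "gaussian",
    sample_id_col: str | None = None,
    recode: Mapping | None = None,
) -> PhenotypeData:
    """Read a TSV phenotype/covariate table.

    Rows with a missing phenotype (or missing covariates) are dropped and
    counted in ``n_dropped``.  For ``family="binomial"`` the phenotype must be
    binary after applying the optional ``recode`` map (e.g. ``{1: 0, 2: 1}``
    for PLINK-style case/control coding).  Sample intersection with the
    genotype matrix is the caller's job (see :func:`align_samples`).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if sample_id_col is None:
        sample_id_col = df.columns[0]
    for col in (sample_id_col, pheno_col, *covar_cols):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    y = pd.to_numeric(df[pheno_col], errors="coerce")
    covs = df[list(covar_cols)].apply(pd.to_numeric, errors="coerce") \
        if covar_cols else pd.DataFrame(index=df.index)
    keep = y.notna()
    if covar_cols:
        keep &= covs.notna().all(axis=1)
    n_dropped = int((~keep).sum())
    df, y, covs = df[keep], y[keep], covs[keep]

    yv = y.to_numpy(dtype=float)
    if recode:
        recoded = np.full_like(yv, np.nan)
        for old, new in recode.items():
            recoded[yv == float(old)] = float(new)
        if np.isnan(recoded).any():
            raise ValueError(f"{path}: phenotype values outside the recode map")
        yv = recoded
    if family == "binomial" and not np.isin(yv, (0.0, 1.0)).all():
        raise ValueError(
            f"{path}: column {pheno_col!r} is not binary 0/1 under "
            "family='binomial' (pass a recode map if coded e.g. 1/2)"
        )
    cov_arr = covs.to_numpy(dtype=float).reshape(len(yv), len(covar_cols))
    for name in covar_cols:
        col = covs[name].to_numpy(dtype=float)
        if len(col) and np.all(col == col[0]):
            warnings.warn(f"covariate {name!r} is constant (collinear with intercept)")
    return PhenotypeData(yv, family, cov_arr, list(covar_cols),
                         list(df[sample_id_col]), n_dropped)


def align_samples(G: GenotypeMatrix, pheno: PhenotypeData):
    """Intersect genotype and phenotype samples, preserving genotype order.

    Returns ``(G_sub, pheno_sub)`` with identical sample id sequences, so row
    ``i`` of dosages, phenotype and covariates all refer to the same sample.
    """
    pos = {sid: i for i, sid in enumerate(pheno.sample_ids)}
    g_idx, p_idx = [], []
    for i, sid in enumerate(G.sample_ids):
        if sid in pos:
            g_idx.append(i)
            p_idx.append(pos[sid])
    if not g_idx:
        raise ConsistencyError("no samples shared between genotypes and phenotypes")
    return G.subset(sample_idx=g_idx), pheno.subset(p_idx)


# ---------------------------------------------------------------------------
# Results table
# ---------------------------------------------------------------------------

def write_results(result, path, gene_path=None) -> None:
    """Write permutation-test results as TSV.

    The pathway table has one row per pathway (input order) with columns
    ``pathway_id``, ``coefficient``, ``p_value``, ``q_value``.  If the result
    carries a gene-level table and ``gene_path`` is given, it is written with
    columns ``pathway_id``, ``gene``, ``coefficient``, ``p_value``,
    ``q_value``.  Floats are written with full round-trip precision.
    """
    frame = result.pathway_frame()
    if frame.empty:
        raise ValueError("refusing to write an empty results table")
    _write_full_precision(frame, path)
    if gene_path is not None and result.gene_table is not None:
        _write_full_precision(result.gene_table, gene_path)


def _write_full_precision(frame: pd.DataFrame, path) -> None:
    out = frame.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(lambda v: repr(float(v)))
    out.to_csv(path, sep="\t", index=False)
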