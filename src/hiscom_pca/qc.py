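"""SNP- and sample-level genotype quality control.

Filters mirror standard SNP-chip practice: SNPs are removed when their minor
allele frequency is at or below a cutoff (common-variant analyses discard
MAF <= 0.05), when their genotype call rate falls below 95%, or when an exact
Hardy-Weinberg equilibrium test rejects at p < 1e-6; samples are kept only
when their own call rate is strictly above 90%.  Residual missing dosages are
then mean-imputed per SNP, which is adequate upstream of PCA summarisation.

The HWE test is the exact conditional test (Wigginton-style): given the
observed allele counts, the two-sided p-value sums the probabilities of all
heterozygote counts no more probable than the observed one.  A chi-square
variant is available via ``method="chisq"`` for users who prefer the
asymptotic test.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .formats import GenotypeMatrix

__all__ = ["QCReport", "hwe_exact_test", "snp_qc", "sample_qc", "impute_missing"]


@dataclass
class QCReport:
    """Bookkeeping for one QC pass.

    ``removed`` attributes each removed SNP/sample to the *first* filter that
    caught it, in the fixed order call rate -> MAF -> HWE, so the counts always
    reconcile with the in/out totals.
    """

    n_snps_in: int
    n_snps_out: int
    n_samples_in: int
    n_samples_out: int
    removed: dict[str, int] = field(default_factory=dict)
    thresholds: dict[str, float] = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = json.dumps(self.__dict__, indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int,
                   method: str = "exact") -> float:
    """Two-sided Hardy-Weinberg equilibrium test for one biallelic SNP.

    Parameters are genotype counts.  The exact test conditions on the allele
    counts and sums the probabilities of all heterozygote counts whose
    probability does not exceed that of the observed count.  A monomorphic
    SNP (one allele absent) returns 1.0 by convention.
    """
    a, h, b = int(n_hom_ref), int(n_het), int(n_hom_alt)
    if min(a, h, b) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = a + h + b
    if n == 0:
        raise ValueError("total genotype count must be positive")
    rare = min(2 * a + h, 2 * b + h)
    if rare == 0:
        return 1.0
    if method == "chisq":
        p_allele = (2 * a + h) / (2 * n)
        exp = n * np.array([p_allele ** 2, 2 * p_allele * (1 - p_allele),
                            (1 - p_allele) ** 2])
        obs = np.array([a, h, b], dtype=float)
        chi2 = float(np.sum((obs - exp) ** 2 / exp))
        return float(stats.chi2.sf(chi2, df=1))
    if method != "exact":
        raise ValueError(f"unknown HWE method {method!r}")

    # Unnormalised probabilities over all heterozygote counts with the same
    # parity as the rare-allele count, built outward from the distribution's
    # mid-point via the stable two-term recurrence.
    het_vals = np.arange(rare % 2, rare + 1, 2)
    mid = (rare * (2 * n - rare)) // (2 * n)
    if (mid - rare) % 2 != 0:
        mid += 1
    probs = {mid: 1.0}
    cur, hval = 1.0, mid
    while hval >= 2 and hval - 2 >= het_vals[0]:
        hom_r = (rare - hval) / 2
        hom_c = n - hval - hom_r
        cur *= hval * (hval - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        hval -= 2
        probs[hval] = cur
    cur, hval = 1.0, mid
    while hval + 2 <= rare:
        hom_r = (rare - hval) / 2
        hom_c = n - hval - hom_r
        cur *= 4.0 * hom_r * hom_c / ((hval + 1) * (hval + 2))
        hval += 2
        probs[hval] = cur
    vals = np.array([probs[v] for v in het_vals])
    vals /= vals.sum()
    p_obs = probs[h] / sum(probs.values())
    p = float(vals[vals <= p_obs * (1 + 1e-12)].sum())
    return min(1.0, p)


def _snp_stats(d: np.ndarray):
    """Per-SNP call rate, MAF and genotype counts from a dosage matrix."""
    n = d.shape[0]
    obs = ~np.isnan(d)
    n_obs = obs.sum(axis=0)
    call_rate = n_obs / n
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        freq = np.nanmean(d, axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    counts = np.stack([
        np.nansum(d == 0.0, axis=0),
        np.nansum(d == 1.0, axis=0),
        np.nansum(d == 2.0, axis=0),
    ])
    return call_rate, maf, counts


def snp_qc(
    G: GenotypeMatrix,
    maf_max_excluded: float = 0.05,
    call_rate_min: float = 0.95,
    hwe_p_min: float = 1e-6,
    hwe_samples: str = "all",
    controls_mask: np.ndarray | None = None,
    hwe_method: str = "exact",
):
    """Remove SNPs failing MAF, call-rate or HWE filters.

    A SNP is removed when MAF <= ``maf_max_excluded`` (the boundary itself is
    excluded), call rate < ``call_rate_min``, or HWE p < ``hwe_p_min``.  MAF
    and HWE use non-missing genotypes only; HWE is computed on all samples by
    default, or on controls only with ``hwe_samples="controls"`` plus a
    boolean ``controls_mask``.

    Returns ``(filtered GenotypeMatrix, QCReport)``.
    """
    if G.n_snps == 0:
        raise ValueError("genotype matrix has no SNPs")
    d = G.dosages
    call_rate, maf, _ = _snp_stats(d)
    if hwe_samples == "controls":
        if controls_mask is None:
            raise ValueError("hwe_samples='controls' requires controls_mask")
        _, _, counts = _snp_stats(d[np.asarray(controls_mask, bool)])
    elif hwe_samples == "all":
        _, _, counts = _snp_stats(d)
    else:
        raise ValueError(f"unknown hwe_samples {hwe_samples!r}")
    hwe_p = np.array([
        hwe_exact_test(counts[0, j], counts[1, j], counts[2, j], method=hwe_method)
        if counts[:, j].sum() > 0 else 1.0
        for j in range(G.n_snps)
    ])

    fail_cr = call_rate < call_rate_min
    fail_maf = np.isnan(maf) | (maf <= maf_max_excluded)
    fail_hwe = hwe_p < hwe_p_min
    keep = ~(fail_cr | fail_maf | fail_hwe)
    if not keep.any():
        raise ValueError("all SNPs removed by QC filters")
    removed = {
        "snp_call_rate": int(fail_cr.sum()),
        "maf": int((fail_maf & ~fail_cr).sum()),
        "hwe": int((fail_hwe & ~fail_cr & ~fail_maf).sum()),
    }
    report = QCReport(
        n_snps_in=G.n_snps, n_snps_out=int(keep.sum()),
        n_samples_in=G.n_samples, n_samples_out=G.n_samples,
        removed=removed,
        thresholds={"maf_max_excluded": maf_max_excluded,
                    "call_rate_min": call_rate_min, "hwe_p_min": hwe_p_min},
    )
    return G.subset(snp_idx=np.flatnonzero(keep)), report


def sample_qc(G: GenotypeMatrix, call_rate_min: float = 0.90,
              exclude_ids=None):
    """Keep samples whose genotype call rate is strictly above the cutoff.

    ``exclude_ids`` accepts a precomputed exclusion list (e.g. sex-consistency
    failures from an external check), applied before the call-rate rule.
    """
    if G.n_samples == 0:
        raise ValueError("genotype matrix has no samples")
    excluded = set(exclude_ids or ())
    pre = np.array([sid not in excluded for sid in G.sample_ids])
    call_rate = (~np.isnan(G.dosages)).mean(axis=1)
    ok = pre & (call_rate > call_rate_min)
    if not ok.any():
        raise ValueError("all samples removed by QC filters")
    removed = {
        "excluded_list": int((~pre).sum()),
        "sample_call_rate": int((pre & ~ok).sum()),
    }
    report = QCReport(
        n_snps_in=G.n_snps, n_snps_out=G.n_snps,
        n_samples_in=G.n_samples, n_samples_out=int(ok.sum()),
        removed=removed, thresholds={"call_rate_min": call_rate_min},
    )
    return G.subset(sample_idx=np.flatnonzero(ok)), report


def impute_missing(G: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing dosage with its SNP's mean observed dosage.

    Column means of the imputed matrix therefore equal the means of the
    observed entries.  Raises if any SNP is entirely missing (such SNPs
    should have been removed by :func:`snp_qc`).
    """
    d = G.dosages
    if not np.isnan(d).any():
        return G
    n_obs = (~np.isnan(d)).sum(axis=0)
    if (n_obs == 0).any():
        bad = G.snp_meta["snp_id"][n_obs == 0].tolist()
        raise ValueError(f"SNPs with no observed genotypes: {bad[:5]}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(d, axis=0)
    filled = np.where(np.isnan(d), means[None, :], d)
    return GenotypeMatrix(filled, G.snp_meta.copy(), list(G.sample_ids),
                          None if G.sample_sex is None else G.sample_sex.copy())
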