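"""Population-structure control: SNP/sample QC, frequency-standardized PCA,
and genomic-inflation diagnostics.

Ancestry within an admixed cohort is modelled by principal components of the
genotype matrix after per-SNP centering at twice the allele frequency and
scaling by the binomial SD sqrt(p(1-p)) — the classical EIGENSTRAT
standardization.  The leading components enter downstream models as
covariates; adequacy of the correction is judged by the genomic inflation
factor, the median association chi-square divided by the null median 0.4549.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

AUTOSOMES = frozenset(str(c) for c in range(1, 23))

#: Median of the 1-df chi-square distribution.
CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, 1))


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs dosage matrix with 0/1/2 coding; NaN marks missing."""

    dosage: np.ndarray  # float array, n_subjects x n_snps
    subjects: list
    snps: list
    chromosomes: list  # per-SNP chromosome label, strings ("1".."22", "X")
    reported_sex: Optional[np.ndarray] = None  # "M"/"F" per subject

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, float)
        n, m = self.dosage.shape
        if len(self.subjects) != n or len(self.snps) != m or len(self.chromosomes) != m:
            raise ValueError("dosage shape inconsistent with id lists")
        valid = np.isnan(self.dosage) | np.isin(self.dosage, [0.0, 1.0, 2.0])
        if not valid.all():
            raise ValueError("dosages must be 0/1/2 or missing")

    def subset(self, subj_idx=None, snp_idx=None) -> "GenotypeMatrix":
        subj_idx = np.arange(len(self.subjects)) if subj_idx is None else np.asarray(subj_idx)
        snp_idx = np.arange(len(self.snps)) if snp_idx is None else np.asarray(snp_idx)
        return GenotypeMatrix(
            self.dosage[np.ix_(subj_idx, snp_idx)],
            [self.subjects[i] for i in subj_idx],
            [self.snps[j] for j in snp_idx],
            [self.chromosomes[j] for j in snp_idx],
            None if self.reported_sex is None else np.asarray(self.reported_sex)[subj_idx],
        )


@dataclass
class PcaResult:
    components: np.ndarray  # subjects x K scores
    eigenvalues: np.ndarray
    K: int


def hwe_test(n_aa: int, n_ab: int, n_bb: int):
    """1-df Pearson chi-square against Hardy-Weinberg proportions.

    Monomorphic SNPs return (0, 1) by convention.
    """
    counts = np.array([n_aa, n_ab, n_bb], float)
    if (counts < 0).any():
        raise ValueError("negative genotype counts")
    n = counts.sum()
    if n <= 0:
        raise ValueError("empty genotype counts")
    p = (2 * n_aa + n_ab) / (2 * n)
    q = 1 - p
    if p <= 0 or q <= 0:
        return 0.0, 1.0
    expected = n * np.array([p * p, 2 * p * q, q * q])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, 1))


@dataclass
class QcThresholds:
    snp_missing_max: float = 0.05
    hwe_p_min: float = 1e-4
    maf_min: float = 0.05
    sample_missing_max: float = 0.03
    # X-heterozygosity sex inference: below -> male, above -> female.
    x_het_male_max: float = 0.05
    x_het_female_min: float = 0.15


def snp_qc(matrix: GenotypeMatrix, thresholds: QcThresholds = QcThresholds()):
    """Drop SNPs that are >5% missing, violate HWE at p<1e-4, are
    non-autosomal, or have minor allele frequency below 0.05.

    Returns the filtered matrix and a per-rule removal report.  A SNP
    failing several rules is counted under each rule it fails; the retained
    set is those failing none, so the filter is idempotent.
    """
    G = matrix.dosage
    n, m = G.shape
    if m == 0 or n == 0:
        raise ValueError("empty genotype matrix")
    missing = np.isnan(G).mean(axis=0)
    autosomal = np.array([c in AUTOSOMES for c in matrix.chromosomes])
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(G, axis=0) / 2.0
    maf = np.minimum(freq, 1 - freq)
    hwe_p = np.ones(m)
    for j in range(m):
        col = G[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            hwe_p[j] = 1.0
            continue
        hwe_p[j] = hwe_test(
            int((col == 2).sum()), int((col == 1).sum()), int((col == 0).sum())
        )[1]
    fail_missing = missing > thresholds.snp_missing_max
    fail_hwe = hwe_p < thresholds.hwe_p_min
    fail_auto = ~autosomal
    fail_maf = ~(maf >= thresholds.maf_min)  # NaN freq fails too
    keep = ~(fail_missing | fail_hwe | fail_auto | fail_maf)
    report = {
        "n_input": int(m),
        "removed_missingness": int(fail_missing.sum()),
        "removed_hwe": int(fail_hwe.sum()),
        "removed_non_autosomal": int(fail_auto.sum()),
        "removed_maf": int(fail_maf.sum()),
        "n_retained": int(keep.sum()),
    }
    if report["n_retained"] == 0:
        raise ValueError("all SNPs removed by QC")
    return matrix.subset(snp_idx=np.where(keep)[0]), report


def x_heterozygosity(matrix: GenotypeMatrix) -> np.ndarray:
    """Per-subject fraction of heterozygous calls among non-missing X SNPs."""
    x_idx = [j for j, c in enumerate(matrix.chromosomes) if c.upper() == "X"]
    if not x_idx:
        raise ValueError("no X-chromosome SNPs present")
    X = matrix.dosage[:, x_idx]
    het = (X == 1).sum(axis=1)
    called = (~np.isnan(X)).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(called > 0, het / called, np.nan)


def infer_sex(matrix: GenotypeMatrix, thresholds: QcThresholds = QcThresholds()):
    het = x_heterozygosity(matrix)
    sex = np.where(het < thresholds.x_het_male_max, "M",
                   np.where(het > thresholds.x_het_female_min, "F", "AMBIGUOUS"))
    return sex.astype(object), het


def sample_qc(matrix: GenotypeMatrix, thresholds: QcThresholds = QcThresholds(),
              check_sex: bool = True):
    """Drop subjects with >3% missing genotypes or reported/inferred sex
    discrepancy (X heterozygosity thresholding; ambiguous subjects are
    flagged but retained)."""
    miss = np.isnan(matrix.dosage).mean(axis=1)
    fail_missing = miss > thresholds.sample_missing_max
    fail_sex = np.zeros(len(matrix.subjects), bool)
    ambiguous: list = []
    if check_sex:
        if matrix.reported_sex is None:
            raise ValueError("reported sex required when sex check is enabled")
        has_x = any(c.upper() == "X" for c in matrix.chromosomes)
        if has_x:
            inferred, _ = infer_sex(matrix, thresholds)
            reported = np.asarray(matrix.reported_sex, object)
            ambiguous = [s for s, g in zip(matrix.subjects, inferred) if g == "AMBIGUOUS"]
            fail_sex = (inferred != "AMBIGUOUS") & (inferred != reported)
    keep = ~(fail_missing | fail_sex)
    report = {
        "n_input": len(matrix.subjects),
        "removed_missingness": int(fail_missing.sum()),
        "removed_sex_discrepancy": int(fail_sex.sum()),
        "ambiguous_sex": ambiguous,
        "n_retained": int(keep.sum()),
    }
    return matrix.subset(subj_idx=np.where(keep)[0]), report


def eigenstrat_pca(matrix: GenotypeMatrix, K: int = 10) -> PcaResult:
    """Top-K PCA of the frequency-standardized genotype matrix.

    Missing dosages are mean-imputed per SNP before standardization;
    each SNP is centered at 2p and scaled by sqrt(p(1-p)).  Components are
    the subject-space scores of the singular decomposition; eigenvalues are
    the variances explained (singular value squared over n-1).
    """
    G = matrix.dosage.copy()
    n, m = G.shape
    col_mean = np.nanmean(G, axis=0)
    nan_r, nan_c = np.where(np.isnan(G))
    G[nan_r, nan_c] = col_mean[nan_c]
    p = col_mean / 2.0
    scale = np.sqrt(np.clip(p * (1 - p), 1e-12, None))
    Z = (G - 2 * p) / scale
    # drop monomorphic columns (zero information after standardization)
    poly = (p > 0) & (p < 1)
    Z = Z[:, poly]
    max_k = int(min(n, Z.shape[1]))
    if K > max_k:
        import warnings

        warnings.warn(f"K={K} exceeds matrix rank bound; reducing to {max_k}")
        K = max_k
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    return PcaResult(
        components=U[:, :K] * s[:K],
        eigenvalues=(s[:K] ** 2) / max(n - 1, 1),
        K=K,
    )


def genomic_inflation(chi_squares: Sequence[float]) -> float:
    """Genomic inflation factor: median observed chi-square / 0.4549."""
    x = np.asarray(chi_squares, float)
    if x.size == 0:
        raise ValueError("no association statistics supplied")
    return float(np.median(x) / CHI2_1DF_MEDIAN)


def association_chi_squares(
    matrix: GenotypeMatrix,
    trait: np.ndarray,
    pcs: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Per-SNP 1-df Wald chi-squares for trait ~ dosage (+ PCs).

    Trait and dosages are residualized on the covariates (intercept + PCs)
    once, then the squared t of the marginal slope is computed per SNP —
    algebraically the partial regression chi-square, vectorized.
    """
    y = np.asarray(trait, float)
    n = y.size
    C = np.ones((n, 1)) if pcs is None else np.column_stack([np.ones(n), pcs])
    Q, _ = np.linalg.qr(C)
    y_r = y - Q @ (Q.T @ y)
    G = matrix.dosage.copy()
    col_mean = np.nanmean(G, axis=0)
    nan_r, nan_c = np.where(np.isnan(G))
    G[nan_r, nan_c] = col_mean[nan_c]
    G_r = G - Q @ (Q.T @ G)
    gg = (G_r ** 2).sum(axis=0)
    gg = np.where(gg > 0, gg, np.nan)
    beta = (G_r * y_r[:, None]).sum(axis=0) / gg
    dof = n - C.shape[1] - 1
    rss = (y_r ** 2).sum() - beta ** 2 * gg
    sigma2 = rss / dof
    chi2 = beta ** 2 * gg / sigma2
    return chi2[np.isfinite(chi2)]
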