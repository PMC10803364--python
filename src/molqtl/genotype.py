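"""Variant-level quality control and genotype summaries.

Implements the QC chain applied before molQTL mapping and GWAS: missingness,
Hardy-Weinberg exact test and MAF filters; composite-LD r-squared and
plink-style sliding-window pruning; PCA of standardized dosages; and the
allele-frequency-standardized genomic relationship matrix used as the
random-effect covariance of the mixed-model GWAS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

MISSING = -1  # dosage sentinel


@dataclass
class FilterReport:
    n_input: int
    n_missingness: int
    n_hwe: int
    n_maf: int
    n_retained: int

    def __str__(self):
        return (
            f"{self.n_input} variants: dropped {self.n_missingness} (missingness), "
            f"{self.n_hwe} (HWE), {self.n_maf} (MAF); retained {self.n_retained}"
        )


def _allele_stats(dosages: np.ndarray):
    """Per-variant (n_called, n_hom_ref, n_het, n_hom_alt, maf) for a
    (samples x variants) dosage matrix with MISSING sentinels."""
    called = dosages != MISSING
    n_called = called.sum(axis=0)
    hom_ref = ((dosages == 0) & called).sum(axis=0)
    het = (dosages == 1).sum(axis=0)
    hom_alt = (dosages == 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        af = (het + 2 * hom_alt) / (2 * np.maximum(n_called, 1))
    maf = np.minimum(af, 1 - af)
    return n_called, hom_ref, het, hom_alt, maf


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact two-sided Hardy-Weinberg test.

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote counts whose probability does not exceed the observed
    one (Wigginton-style exact test).
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("total genotype count must be positive")
    n_rare = n_het + 2 * min(n_hom_ref, n_hom_alt)
    # heterozygote count has the parity of the rare allele count
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    hom_rare = (n_rare - hets) // 2
    hom_common = n - hets - hom_rare
    valid = hom_common >= 0
    hets, hom_rare, hom_common = hets[valid], hom_rare[valid], hom_common[valid]
    logp = (
        gammaln(n + 1)
        - gammaln(hom_rare + 1)
        - gammaln(hets + 1)
        - gammaln(hom_common + 1)
        + hets * np.log(2.0)
        + gammaln(n_rare + 1)
        + gammaln(2 * n - n_rare + 1)
        - gammaln(2 * n + 1)
    )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    obs = prob[hets == n_het][0]
    return float(min(1.0, prob[prob <= obs * (1 + 1e-12)].sum()))


def filter_variants(
    variants: pd.DataFrame,
    dosages: np.ndarray,
    max_missing: float = 0.5,
    hwe_alpha: float = 1e-8,
    min_maf: float = 0.01,
):
    """Apply the missingness, HWE and MAF filters in that order.

    Returns ``(variants, dosages, report)`` with MAF recomputed on the
    survivors.  A variant failing several filters is counted against the
    first one that catches it.
    """
    if len(variants) == 0:
        raise ValueError("empty variant table")
    n = dosages.shape[0]
    n_called, hom_ref, het, hom_alt, maf = _allele_stats(dosages)
    miss_fail = (1 - n_called / n) > max_missing
    hwe_p = np.ones(len(variants))
    for j in np.nonzero(~miss_fail)[0]:
        hwe_p[j] = hwe_exact_test(int(hom_ref[j]), int(het[j]), int(hom_alt[j]))
    hwe_fail = (~miss_fail) & (hwe_p < hwe_alpha)
    maf_fail = (~miss_fail) & (~hwe_fail) & (maf < min_maf)
    keep = ~(miss_fail | hwe_fail | maf_fail)
    report = FilterReport(
        n_input=len(variants),
        n_missingness=int(miss_fail.sum()),
        n_hwe=int(hwe_fail.sum()),
        n_maf=int(maf_fail.sum()),
        n_retained=int(keep.sum()),
    )
    out = variants.loc[keep].copy()
    out["maf"] = maf[keep]
    return out, dosages[:, keep], report


def ld_r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Squared Pearson correlation of dosages (composite LD); pairs with a
    missing value in either vector are excluded."""
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors must have equal length")
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok], b[ok]
    if len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
        raise ValueError("constant dosage vector")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _r2_matrix(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    sd[sd == 0] = np.inf
    C = (Xc / sd).T @ (Xc / sd) / X.shape[0]
    return C**2


def ld_prune(
    variants: pd.DataFrame,
    dosages: np.ndarray,
    window_variants: int = 1000,
    step: int = 5,
    r2_threshold: float = 0.2,
) -> list:
    """Greedy sliding-window LD pruning (plink ``--indep-pairwise`` style).

    Within each window of ``window_variants`` position-sorted variants,
    while any retained pair exceeds ``r2_threshold`` the member with the
    smaller MAF is removed (tie broken against the later position); the
    window then advances by ``step`` variants.  Returns retained ids.
    """
    if window_variants < 2:
        raise ValueError("window must span at least 2 variants")
    if not variants["pos"].is_monotonic_increasing:
        order = np.argsort(variants["pos"].to_numpy(), kind="stable")
    else:
        order = np.arange(len(variants))
    ids = variants["id"].to_numpy()[order]
    maf = variants["maf"].to_numpy()[order]
    X = dosages[:, order]
    m = len(ids)
    removed = np.zeros(m, dtype=bool)
    for start in range(0, max(1, m - 1), step):
        stop = min(start + window_variants, m)
        live = [j for j in range(start, stop) if not removed[j]]
        if len(live) < 2:
            if stop == m:
                break
            continue
        r2 = _r2_matrix(X[:, live])
        np.fill_diagonal(r2, 0.0)
        while True:
            j, k = np.unravel_index(np.argmax(r2), r2.shape)
            if r2[j, k] <= r2_threshold:
                break
            # drop smaller MAF; tie -> later position
            drop = j if maf[live[j]] < maf[live[k]] else k
            if maf[live[j]] == maf[live[k]]:
                drop = max(j, k)
            removed[live[drop]] = True
            r2[drop, :] = 0.0
            r2[:, drop] = 0.0
        if stop == m:
            break
    return [ids[j] for j in range(m) if not removed[j]]


@dataclass
class PCAResult:
    scores: pd.DataFrame           # samples x components
    explained_variance_ratio: np.ndarray

    def __post_init__(self):
        assert np.all(np.diff(self.explained_variance_ratio) <= 1e-12)


def genotype_pca(
    dosages: np.ndarray, n_components: int = 3, samples: list | None = None
) -> PCAResult:
    """PCA of centered, variance-standardized dosages."""
    n, m = dosages.shape
    if n_components > min(n, m):
        raise ValueError("n_components exceeds matrix rank bound")
    X = dosages.astype(float)
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    X = X[:, keep] / sd[keep]
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :n_components] * s[:n_components]
    evr = (s**2) / (s**2).sum()
    if samples is None:
        samples = [f"S{i}" for i in range(n)]
    return PCAResult(
        scores=pd.DataFrame(
            scores, index=samples, columns=[f"PC{k+1}" for k in range(n_components)]
        ),
        explained_variance_ratio=evr[:n_components],
    )


@dataclass
class GRM:
    matrix: np.ndarray
    n_variants_used: int
    samples: list | None = None

    def __post_init__(self):
        assert np.allclose(self.matrix, self.matrix.T, atol=1e-10)

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.matrix).min())


def compute_grm(dosages: np.ndarray, samples: list | None = None) -> GRM:
    """GCTA-style GRM: ``K_jk = (1/m) sum_v (x_jv - 2 p_v)(x_kv - 2 p_v) /
    (2 p_v (1 - p_v))`` over variants with 0 < p < 1."""
    X = dosages.astype(float)
    p = X.mean(axis=0) / 2.0
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("monomorphic variant passed to compute_grm")
    Z = (X - 2 * p) / np.sqrt(2 * p * (1 - p))
    m = X.shape[1]
    K = Z @ Z.T / m
    K = (K + K.T) / 2.0
    return GRM(matrix=K, n_variants_used=m, samples=samples)
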