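"""Allelic fold change and haplotype-level allelic imbalance.

The effect size of a cis-eQTL is expressed as the log2 allelic fold change
(aFC): the expression ratio of the haplotype carrying the alternative
allele over the haplotype carrying the reference allele of the regulatory
variant.  Two estimators are implemented:

* ``estimate_afc`` fits the aFC mean model to total (size-factor
  normalized, log-transformed) gene counts against eVariant dosage:
  ``E[expr | g] = base * ((2 - g) + g * 2**delta) / 2``.
* ``individual_log_afc`` reads the fold change directly off
  haplotype-resolved counts of heterozygous carriers; comparing
  heterozygotes (imbalance expected) with homozygotes (none expected) by
  Wilcoxon rank-sum validates cis action independently of the regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from statsmodels.stats.multitest import multipletests

from .cis import residualize
from .sim import afc_dosage_factor

AFC_CAP = np.log2(100.0)


def median_of_ratios_size_factors(counts: pd.DataFrame) -> pd.Series:
    """DESeq-style size factors: median across genes of the ratio of each
    sample's count to the geometric-mean reference, over genes with no
    zero count."""
    logc = np.log(counts.where(counts > 0))
    ref = logc.mean(axis=1)
    ok = np.isfinite(ref)
    if not ok.any():
        raise ValueError("no gene without zero counts; cannot form reference")
    ratios = logc.loc[ok].sub(ref[ok], axis=0)
    return np.exp(ratios.median(axis=0))


@dataclass
class AFCEstimate:
    gene: str
    variant: str
    slope_afc: float
    se: float
    capped: bool


def estimate_afc(
    counts: np.ndarray,
    dosages: np.ndarray,
    covariates: np.ndarray | None = None,
    size_factors: np.ndarray | None = None,
    gene: str = "",
    variant: str = "",
) -> AFCEstimate:
    """Fit the log2 allelic fold change of one eQTL from total gene counts.

    Counts are divided by size factors and log2(x + 1)-transformed; delta
    maximizes the Gaussian likelihood of the transformed counts around
    ``log2(((2 - g) + g * 2**delta) / 2) + intercept + covariates``,
    profiled by 1-D bounded optimization with the linear part solved
    exactly at each delta.  The estimate is clamped to |delta| <= log2(100).
    """
    c = np.asarray(counts, dtype=float)
    g = np.asarray(dosages, dtype=float)
    if np.all(c == 0):
        raise ValueError("all-zero counts")
    if len(np.unique(g)) < 2:
        raise ValueError("need >= 2 genotype classes")
    if size_factors is not None:
        c = c / np.asarray(size_factors, dtype=float)
    y = np.log2(c + 1.0)
    n = len(y)
    C = np.ones((n, 1))
    if covariates is not None and np.size(covariates):
        C = np.column_stack([C, covariates])

    def rss(delta):
        mu = np.log2(afc_dosage_factor(g, delta))
        r = y - mu
        beta, *_ = np.linalg.lstsq(C, r, rcond=None)
        e = r - C @ beta
        return float(e @ e)

    opt = minimize_scalar(rss, bounds=(-AFC_CAP, AFC_CAP), method="bounded",
                          options={"xatol": 1e-7})
    delta = float(opt.x)
    capped = bool(abs(delta) >= AFC_CAP - 1e-6)
    # curvature-based standard error from the profiled objective
    h = 1e-3
    d2 = (rss(delta + h) - 2 * rss(delta) + rss(delta - h)) / h**2
    sigma2 = rss(delta) / max(n - C.shape[1] - 1, 1)
    se = float(np.sqrt(2 * sigma2 / d2)) if d2 > 0 else np.inf
    return AFCEstimate(gene=gene, variant=variant, slope_afc=delta, se=se, capped=capped)


def afc_concordance(afc: pd.Series, slopes: pd.Series) -> float:
    """Spearman correlation between slope_aFC and the linear-model beta
    over shared variant-gene pairs."""
    shared = afc.index.intersection(slopes.index)
    if len(shared) < 10:
        raise ValueError("need at least 10 shared pairs")
    rho, _ = stats.spearmanr(afc.loc[shared], slopes.loc[shared])
    return float(rho)


def individual_log_afc(
    table: pd.DataFrame, pseudocount: float = 0.5, min_coverage: int = 8
) -> pd.DataFrame:
    """Per-sample log2 haplotype ratios from haplotype-resolved counts.

    ``table`` columns: gene, sample, genotype (dosage at the top eVariant),
    alt_count, ref_count.  For heterozygotes the ratio is alt-linked over
    ref-linked; for homozygotes the haplotype labeling is arbitrary, so the
    ratio carries no sign information and serves as the null reference.
    Samples with coverage below ``min_coverage`` are excluded.
    """
    t = table.copy()
    total = t["alt_count"] + t["ref_count"]
    t = t[total >= min_coverage].copy()
    t["log2_ratio"] = np.log2(
        (t["alt_count"] + pseudocount) / (t["ref_count"] + pseudocount)
    )
    t["het"] = t["genotype"] == 1
    return t


@dataclass
class ImbalanceResult:
    gene: str
    variant: str
    median_het_log2: float
    pval: float
    n_het: int
    n_hom: int
    qvalue: float = np.nan


def imbalance_test(
    ratios_het: np.ndarray,
    ratios_hom: np.ndarray,
    gene: str = "",
    variant: str = "",
    signed: bool = False,
) -> ImbalanceResult | None:
    """Wilcoxon rank-sum of haplotype imbalance, heterozygotes vs
    homozygotes at the top eVariant.

    By default the magnitudes |log2 ratio| are compared (the haplotype
    labeling of homozygotes is arbitrary); ``signed=True`` compares the raw
    ratios.  Returns None when either group has fewer than 10 samples.
    """
    het = np.asarray(ratios_het, float)
    hom = np.asarray(ratios_hom, float)
    if len(het) < 10 or len(hom) < 10:
        return None
    a, b = (het, hom) if signed else (np.abs(het), np.abs(hom))
    if np.all(a == a[0]) and np.all(b == a[0]):
        p = 1.0
    else:
        # exact null distribution for small tie-free groups, normal
        # approximation otherwise (scipy's automatic switch)
        p = float(
            stats.mannwhitneyu(a, b, alternative="two-sided", method="auto").pvalue
        )
    return ImbalanceResult(
        gene=gene,
        variant=variant,
        median_het_log2=float(np.median(het)),
        pval=p,
        n_het=len(het),
        n_hom=len(hom),
    )


def imbalance_scan(
    ratio_table: pd.DataFrame, fdr: float = 0.05, signed: bool = False
) -> pd.DataFrame:
    """Run the imbalance test per gene and attach Benjamini-Hochberg
    q-values across genes at the requested FDR."""
    rows = []
    for (gene, variant), grp in ratio_table.groupby(["gene", "variant"], sort=True):
        res = imbalance_test(
            grp.loc[grp["het"], "log2_ratio"].to_numpy(),
            grp.loc[~grp["het"], "log2_ratio"].to_numpy(),
            gene=gene,
            variant=variant,
            signed=signed,
        )
        if res is not None:
            rows.append(vars(res))
    out = pd.DataFrame(
        rows,
        columns=["gene", "variant", "median_het_log2", "pval", "n_het", "n_hom", "qvalue"],
    )
    if len(out):
        rej, q, *_ = multipletests(out["pval"], alpha=fdr, method="fdr_bh")
        out["qvalue"] = q
        out["significant"] = rej
    else:
        out["significant"] = pd.Series(dtype=bool)
    return out


def tss_proximity_enrichment(
    significant: np.ndarray, within_window: np.ndarray
) -> tuple[float, float]:
    """Fisher's exact test of imbalance-significance against TSS proximity.

    Returns ``(odds_ratio, pval)`` for the 2x2 table of
    (significant vs not) x (variant within the TSS window vs not).
    """
    sig = np.asarray(significant, bool)
    win = np.asarray(within_window, bool)
    table = np.array(
        [
            [np.sum(sig & win), np.sum(sig & ~win)],
            [np.sum(~sig & win), np.sum(~sig & ~win)],
        ]
    )
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise ValueError("degenerate margin in the contingency table")
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)
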