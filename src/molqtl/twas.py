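"""Transcriptome-wide association and colocalization filter cascade.

Per-phenotype elastic-net prediction models are trained on cis dosages of
the molQTL cohort; gene-level association with the GWAS trait is then
computed from summary statistics alone (S-PrediXcan statistic)

    Z_g = sum_l w_l (sigma_l / sigma_g) (beta_l / se_l),
    sigma_g^2 = w' Gamma w,

with the model-training cohort as the LD reference.  Significant TWAS
genes near a GWAS peak are tested for a shared causal variant by
approximate-Bayes-factor colocalization: per-variant Wakefield log-ABFs
for both traits combine into posterior probabilities of the five causal
configurations (H0 none, H1/H2 one trait only, H3 two distinct variants,
H4 one shared variant).  The cascade retains genes with PP.H4 > 0.8 and
PP.H3 < 0.5, mirroring the discovery filter for fertility-associated
genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp


# ---------------------------------------------------------------------------
# prediction models
# ---------------------------------------------------------------------------

@dataclass
class PredictionModel:
    phenotype_id: str
    variant_ids: list
    weights: np.ndarray
    rho_avg: float
    zscore_pval: float
    n_folds: int
    alpha: float = np.nan

    @property
    def nonzero(self) -> dict:
        return {
            v: float(w)
            for v, w in zip(self.variant_ids, self.weights)
            if w != 0.0
        }


def train_prediction_model(
    phenotype: np.ndarray,
    dosages: np.ndarray,
    variant_ids,
    covariates: np.ndarray | None = None,
    folds: int = 10,
    l1_ratio: float = 0.5,
    seed: int = 0,
    phenotype_id: str = "",
) -> PredictionModel:
    """Elastic-net cis prediction model with cross-validated performance.

    The covariate-residualized phenotype is regressed on cis dosages with
    elastic-net penalty (mixing 0.5), penalty strength chosen by inner
    cross-validation.  Performance comes from an outer K-fold split:
    ``rho_avg`` is the mean across folds of the Spearman correlation
    between out-of-fold predictions and observations, and ``zscore_pval``
    a one-sided p from a Stouffer combination of the per-fold Fisher-z
    correlation scores.
    """
    from sklearn.exceptions import ConvergenceWarning
    from sklearn.linear_model import ElasticNet, ElasticNetCV
    from sklearn.model_selection import KFold
    import warnings

    y = np.asarray(phenotype, float)
    G = np.asarray(dosages, float)
    n = len(y)
    if n < 30:
        raise ValueError("need at least 30 samples")
    if G.shape[1] < 2:
        raise ValueError("need at least 2 cis variants")
    from .cis import residualize

    yr = residualize(y, covariates)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        cv_model = ElasticNetCV(
            l1_ratio=l1_ratio,
            alphas=50,
            cv=min(folds, 5),
            random_state=seed,
            max_iter=2000,
        )
        cv_model.fit(G, yr)
        alpha = float(cv_model.alpha_)

        for attempt in range(5):
            kf = KFold(n_splits=folds, shuffle=True, random_state=seed + attempt)
            rhos, zs, ok = [], [], True
            preds = np.full(n, np.nan)
            for train, test in kf.split(G):
                if np.ptp(yr[train]) == 0:
                    ok = False
                    break
                en = ElasticNet(alpha=alpha, l1_ratio=l1_ratio, max_iter=2000)
                en.fit(G[train], yr[train])
                p = en.predict(G[test])
                preds[test] = p
                if np.ptp(p) == 0 or np.ptp(yr[test]) == 0:
                    rho = 0.0
                else:
                    rho = stats.spearmanr(p, yr[test]).statistic
                    if not np.isfinite(rho):
                        rho = 0.0
                rhos.append(rho)
                nf = len(test)
                if nf > 3:
                    zs.append(np.arctanh(np.clip(rho, -0.999999, 0.999999)) * np.sqrt(nf - 3))
            if ok:
                break
        else:
            raise RuntimeError("could not form non-degenerate folds")

        final = ElasticNet(alpha=alpha, l1_ratio=l1_ratio, max_iter=5000)
        final.fit(G, yr)

    rho_avg = float(np.mean(rhos))
    if zs:
        stouffer = float(np.sum(zs) / np.sqrt(len(zs)))
        zscore_pval = float(stats.norm.sf(stouffer))
    else:
        zscore_pval = 1.0
    return PredictionModel(
        phenotype_id=phenotype_id,
        variant_ids=list(variant_ids),
        weights=final.coef_.copy(),
        rho_avg=rho_avg,
        zscore_pval=zscore_pval,
        n_folds=folds,
        alpha=alpha,
    )


def performance_filter(
    models: list[PredictionModel],
    max_zscore_pval: float = 0.05,
    min_rho: float = 0.1,
) -> list[PredictionModel]:
    """Keep high-performance models: zscore_pval < 0.05 AND rho_avg > 0.1
    (both strict, matching the discovery filter)."""
    return [
        m
        for m in models
        if m.zscore_pval < max_zscore_pval and m.rho_avg > min_rho
    ]


# ---------------------------------------------------------------------------
# S-PrediXcan
# ---------------------------------------------------------------------------

@dataclass
class LdReference:
    """Variant covariance from the model-training cohort."""

    variant_ids: list
    covariance: np.ndarray       # Gamma over the variants
    sd: np.ndarray               # per-variant dosage standard deviation

    @classmethod
    def from_dosages(cls, dosages: np.ndarray, variant_ids) -> "LdReference":
        G = np.asarray(dosages, float)
        cov = np.cov(G.T, ddof=1)
        cov = np.atleast_2d(cov)
        return cls(
            variant_ids=list(variant_ids),
            covariance=cov,
            sd=np.sqrt(np.diag(cov)),
        )


@dataclass
class TwasResult:
    phenotype_id: str
    zscore: float
    pval: float
    n_model_variants: int
    n_missing: int = 0


def spredixcan_zscore(
    model: PredictionModel,
    gwas_stats: pd.DataFrame,
    reference: LdReference,
) -> TwasResult:
    """Summary-statistic TWAS association for one prediction model.

    ``gwas_stats`` is indexed by variant id with columns ``beta`` and
    ``se``.  Model variants missing from the summary statistics or the
    reference are dropped (logged in ``n_missing``); an uninformative
    model (sigma_g = 0) raises.
    """
    ref_index = {v: j for j, v in enumerate(reference.variant_ids)}
    used_w, used_ref_idx, zsum_terms = [], [], []
    n_missing = 0
    for v, w in zip(model.variant_ids, model.weights):
        if w == 0.0:
            continue
        if v not in gwas_stats.index or v not in ref_index:
            n_missing += 1
            continue
        used_w.append(w)
        used_ref_idx.append(ref_index[v])
        row = gwas_stats.loc[v]
        zsum_terms.append((w, reference.sd[ref_index[v]], row["beta"] / row["se"]))
    if not used_w:
        raise ValueError("model has no usable non-zero weights")
    w = np.array(used_w)
    Gam = reference.covariance[np.ix_(used_ref_idx, used_ref_idx)]
    sigma_g2 = float(w @ Gam @ w)
    if sigma_g2 <= 0:
        raise ValueError("predicted expression has zero variance in reference")
    sigma_g = np.sqrt(sigma_g2)
    z = sum(wi * (sl / sigma_g) * zi for wi, sl, zi in zsum_terms)
    return TwasResult(
        phenotype_id=model.phenotype_id,
        zscore=float(z),
        pval=float(2 * stats.norm.sf(abs(z))),
        n_model_variants=len(w),
        n_missing=n_missing,
    )


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


# ---------------------------------------------------------------------------
# colocalization
# ---------------------------------------------------------------------------

def wakefield_abf(beta: np.ndarray, se: np.ndarray, prior_sd: float = 0.15) -> np.ndarray:
    """Per-variant Wakefield log approximate Bayes factor.

    ``lABF = 0.5 log(1 - r) + 0.5 z^2 r`` with ``r = W / (W + V)``,
    ``W = prior_sd^2``, ``V = se^2``, ``z = beta / se``.
    """
    se = np.asarray(se, float)
    beta = np.asarray(beta, float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    if prior_sd <= 0:
        raise ValueError("prior standard deviation must be positive")
    V = se**2
    W = prior_sd**2
    r = W / (W + V)
    z = beta / se
    return 0.5 * np.log(1 - r) + 0.5 * z**2 * r


@dataclass
class ColocResult:
    pp_h0: float
    pp_h1: float
    pp_h2: float
    pp_h3: float
    pp_h4: float
    best_shared_variant: str
    n_variants: int
    snp_pp_h4: pd.Series = field(repr=False, default=None)

    def posteriors(self) -> np.ndarray:
        return np.array([self.pp_h0, self.pp_h1, self.pp_h2, self.pp_h3, self.pp_h4])


def coloc_abf(
    stats1: pd.DataFrame,
    stats2: pd.DataFrame,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    prior_sd1: float = 0.15,
    prior_sd2: float = 0.15,
) -> ColocResult:
    """Approximate-Bayes-factor colocalization of two traits in one region.

    ``stats1``/``stats2`` are indexed by variant id with columns ``beta``
    and ``se``; only shared variants enter.  Hypothesis sums run in log
    space: H1/H2 sum single-trait ABFs, H3 sums products over distinct
    variant pairs, H4 over the same variant; posteriors are proportional
    to {1, p1 H1, p2 H2, p1 p2 H3, p12 H4}.
    """
    shared = stats1.index.intersection(stats2.index)
    if len(shared) < 2:
        raise ValueError("need >= 2 shared variants")
    l1 = wakefield_abf(
        stats1.loc[shared, "beta"].to_numpy(),
        stats1.loc[shared, "se"].to_numpy(),
        prior_sd1,
    )
    l2 = wakefield_abf(
        stats2.loc[shared, "beta"].to_numpy(),
        stats2.loc[shared, "se"].to_numpy(),
        prior_sd2,
    )
    lsum = l1 + l2
    lh1 = logsumexp(l1)
    lh2 = logsumexp(l2)
    lh4 = logsumexp(lsum)
    # H3: sum_{i != j} ABF1_i ABF2_j = H1 * H2 - H4 in log space
    lh3 = logsumexp([lh1 + lh2, lh4], b=[1.0, -1.0])
    if not np.isfinite(lh3):
        lh3 = -np.inf

    terms = np.array(
        [
            0.0,
            np.log(p1) + lh1,
            np.log(p2) + lh2,
            np.log(p1) + np.log(p2) + lh3 if np.isfinite(lh3) else -np.inf,
            (np.log(p12) + lh4) if p12 > 0 else -np.inf,
        ]
    )
    denom = logsumexp(terms[np.isfinite(terms)])
    pp = np.where(np.isfinite(terms), np.exp(terms - denom), 0.0)
    snp_pp = pd.Series(np.exp(lsum - lh4), index=shared, name="snp_pp_h4")
    best = str(snp_pp.idxmax())
    return ColocResult(
        pp_h0=float(pp[0]),
        pp_h1=float(pp[1]),
        pp_h2=float(pp[2]),
        pp_h3=float(pp[3]),
        pp_h4=float(pp[4]),
        best_shared_variant=best,
        n_variants=len(shared),
        snp_pp_h4=snp_pp,
    )


def coloc_filter(records: pd.DataFrame, min_h4: float = 0.8, max_h3: float = 0.5) -> pd.DataFrame:
    """Retain colocalizations with PP.H4 > 0.8 and PP.H3 < 0.5."""
    return records[(records["pp_h4"] > min_h4) & (records["pp_h3"] < max_h3)].copy()


# ---------------------------------------------------------------------------
# filter cascade
# ---------------------------------------------------------------------------

@dataclass
class CascadeRecord:
    phenotype_id: str
    tissue: str
    modality: str
    twas_z: float
    twas_p: float
    passed_twas: bool
    peak_variant: str = ""
    pp_h3: float = np.nan
    pp_h4: float = np.nan
    best_shared_variant: str = ""
    retained: bool = False


class FilterCascade:
    """The gene-nomination cascade: TWAS -> Bonferroni -> secondary
    performance filter -> coloc within +/- 5 Mb of GWAS peaks -> PP filter.

    Parameters
    ----------
    models : list of high-performance :class:`PredictionModel`
        (already through :func:`performance_filter`).
    gwas_stats : DataFrame indexed by variant with beta, se, chrom, pos.
    reference : :class:`LdReference` covering all model variants.
    anchors : DataFrame indexed by phenotype id with chrom, pos.
    tissue, modality : labels attached to the records.
    """

    def __init__(
        self,
        models,
        gwas_stats: pd.DataFrame,
        reference: LdReference,
        anchors: pd.DataFrame,
        tissue: str = "",
        modality: str = "expression",
        coloc_window: int = 5_000_000,
    ):
        self.models = models
        self.gwas_stats = gwas_stats
        self.reference = reference
        self.anchors = anchors
        self.tissue = tissue
        self.modality = modality
        self.coloc_window = coloc_window

    def run(
        self,
        peaks,
        molqtl_stats_lookup,
        alpha: float = 0.05,
        p1: float = 1e-4,
        p2: float = 1e-4,
        p12: float = 1e-5,
    ) -> "CascadeResults":
        """Execute the cascade.

        ``peaks`` is the list of GWAS :class:`~molqtl.gwas.QtlPeak`;
        ``molqtl_stats_lookup(phenotype_id, variant_ids)`` must return the
        molQTL cohort's per-variant ``beta``/``se`` frame for the coloc
        window.
        """
        if not self.models:
            raise ValueError("cascade stage 'twas': no prediction models supplied")
        if self.gwas_stats is None or len(self.gwas_stats) == 0:
            raise ValueError("cascade stage 'twas': missing GWAS summary statistics")
        twas = []
        for m in self.models:
            try:
                twas.append(spredixcan_zscore(m, self.gwas_stats, self.reference))
            except ValueError:
                continue
        n_tests = len(twas)
        if n_tests == 0:
            return CascadeResults(pd.DataFrame(), [], np.nan)
        thr = bonferroni_threshold(alpha, n_tests)
        passed = [t for t in twas if t.pval < thr]
        # secondary filter: alpha over the count surviving the first stage
        thr2 = bonferroni_threshold(alpha, max(len(passed), 1))
        passed = [t for t in passed if t.pval < thr2]
        passed_ids = {t.phenotype_id for t in passed}

        records = []
        for t in twas:
            rec = CascadeRecord(
                phenotype_id=t.phenotype_id,
                tissue=self.tissue,
                modality=self.modality,
                twas_z=t.zscore,
                twas_p=t.pval,
                passed_twas=t.phenotype_id in passed_ids,
            )
            if rec.passed_twas:
                anchor = self.anchors.loc[t.phenotype_id]
                for peak in peaks:
                    if peak.chrom != anchor["chrom"]:
                        continue
                    lead_pos = self.gwas_stats.loc[peak.lead_variant, "pos"]
                    if abs(lead_pos - anchor["pos"]) > self.coloc_window:
                        continue
                    window_vars = self.gwas_stats[
                        (self.gwas_stats["chrom"] == peak.chrom)
                        & (np.abs(self.gwas_stats["pos"] - lead_pos) <= self.coloc_window)
                    ].index
                    mol = molqtl_stats_lookup(t.phenotype_id, window_vars)
                    if mol is None or len(mol) < 2:
                        continue
                    try:
                        cres = coloc_abf(
                            mol,
                            self.gwas_stats.loc[window_vars, ["beta", "se"]].dropna(),
                            p1=p1,
                            p2=p2,
                            p12=p12,
                        )
                    except ValueError:
                        continue
                    if not np.isfinite(rec.pp_h4) or cres.pp_h4 > rec.pp_h4:
                        rec.peak_variant = peak.lead_variant
                        rec.pp_h3 = cres.pp_h3
                        rec.pp_h4 = cres.pp_h4
                        rec.best_shared_variant = cres.best_shared_variant
            records.append(rec)
        table = pd.DataFrame([vars(r) for r in records])
        if len(table):
            table["retained"] = (
                table["passed_twas"]
                & (table["pp_h4"] > 0.8)
                & (table["pp_h3"] < 0.5)
            ).fillna(False)
        return CascadeResults(table, twas, thr)


class CascadeResults:
    """Cascade verdicts with one row per TWAS-tested phenotype."""

    def __init__(self, table: pd.DataFrame, twas: list, threshold: float):
        self.table = table
        self.twas = twas
        self.bonferroni = threshold

    @property
    def retained(self) -> pd.DataFrame:
        if len(self.table) == 0:
            return self.table
        return self.table[self.table["retained"]]

    def summary(self) -> str:
        n = len(self.table)
        lines = [
            "TWAS + colocalization cascade",
            "=============================",
            f"models tested        {n}",
            f"Bonferroni p         {self.bonferroni:.3g}" if n else "",
            f"passed TWAS          {int(self.table['passed_twas'].sum()) if n else 0}",
            f"retained (coloc)     {len(self.retained)}",
        ]
        for _, r in self.retained.iterrows():
            lines.append(
                f"  {r['phenotype_id']} z={r['twas_z']:+.2f} p={r['twas_p']:.3g} "
                f"PP.H4={r['pp_h4']:.2f} shared={r['best_shared_variant']}"
            )
        return "\n".join(x for x in lines if x)
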