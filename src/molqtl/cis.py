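"""cis and trans molQTL mapping.

The mapping scheme follows the standard cohort-eQTL design: phenotypes and
dosages are residualized on covariates, each phenotype is tested against
every variant within 1 Mb of its anchor (TSS for expression, intron-cluster
start for splicing), and per-phenotype multiple testing across the cis
window is corrected by permuting the phenotype (1000 permutations by
default) and fitting a Beta distribution to the permutation minima.  A
genome-wide 5% FDR over the beta-adjusted p-values (Storey q-values) then
yields per-phenotype nominal thresholds, which drive the forward/backward
conditional pass for independent signals.  Splicing phenotypes of one gene
are permuted jointly and summarized by the group-minimum p-value.

Trans associations are scanned beyond 5 Mb of the anchor (or on other
chromosomes) with a permutation-rank FDR, and filtered against linkage
with the gene's own cis signals.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import betainc, digamma, polygamma

from .io import GenotypeData


def _pheno_seed(seed: int, label: str) -> np.random.Generator:
    h = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return np.random.default_rng(int.from_bytes(h[:4], "little"))


# ---------------------------------------------------------------------------
# linear-algebra core
# ---------------------------------------------------------------------------

def residualize(M: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Residuals of each column of ``M`` on [1, covariates]."""
    M = np.asarray(M, dtype=float)
    one_d = M.ndim == 1
    if one_d:
        M = M[:, None]
    n = M.shape[0]
    C = np.ones((n, 1))
    if covariates is not None and covariates.size:
        C = np.column_stack([C, covariates])
    beta, *_ = np.linalg.lstsq(C, M, rcond=None)
    R = M - C @ beta
    return R[:, 0] if one_d else R


def nominal_scan(
    phenotype: np.ndarray,
    dosages: np.ndarray,
    covariates: np.ndarray | None = None,
    variant_ids=None,
) -> pd.DataFrame:
    """Per-variant linear association of one phenotype with cis dosages.

    Phenotype and dosages are residualized on the covariates (with
    intercept), then each variant is tested by simple regression of the
    residuals; p-values use a t distribution with ``n - c - 2`` degrees of
    freedom, matching full-design least squares.
    """
    y = np.asarray(phenotype, dtype=float)
    G = np.asarray(dosages, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    n = len(y)
    c = 0 if covariates is None else np.atleast_2d(covariates).shape[1]
    dof = n - c - 2
    if dof < 1:
        raise ValueError("fewer samples than covariates + 2")
    yr = residualize(y, covariates)
    Gr = residualize(G, covariates)
    syy = yr @ yr
    sxx = (Gr * Gr).sum(axis=0)
    sxy = yr @ Gr
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = sxy / sxx
        r2 = np.clip(sxy**2 / (sxx * syy), 0.0, 1.0)
        tstat2 = r2 * dof / np.maximum(1.0 - r2, 1e-300)
        se = np.abs(slope) / np.sqrt(np.maximum(tstat2, 1e-300))
    pval = stats.f.sf(tstat2, 1, dof)
    out = pd.DataFrame(
        {"slope": slope, "se": se, "pval": np.clip(pval, 1e-300, 1.0), "r2": r2}
    )
    out["dof"] = dof
    if variant_ids is not None:
        out.insert(0, "variant", np.asarray(variant_ids))
    return out


def _r2_to_pval(r2: np.ndarray, dof: int) -> np.ndarray:
    t2 = r2 * dof / np.maximum(1.0 - r2, 1e-300)
    return np.clip(stats.f.sf(t2, 1, dof), 1e-300, 1.0)


def _perm_max_r2(
    yr: np.ndarray, Gn: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Max r^2 over variants for ``n_perm`` permutations of the residualized
    phenotype (covariates and genotypes fixed)."""
    n = len(yr)
    ynorm = np.linalg.norm(yr)
    out = np.empty(n_perm)
    block = max(1, int(2e7 / max(Gn.size + 8 * n, 1)))
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        # permutations via row-wise argsort of uniforms (vectorized shuffle)
        P = yr[np.argsort(rng.random((b, n)), axis=1)]
        R = (P @ Gn) / ynorm
        out[done : done + b] = (R**2).max(axis=1)
        done += b
    return out


# ---------------------------------------------------------------------------
# beta approximation
# ---------------------------------------------------------------------------

def fit_beta_approx(pvalues: np.ndarray, max_iter: int = 100, tol: float = 1e-8):
    """Maximum-likelihood Beta(k, n) fit to permutation minimum p-values.

    Newton iteration on the log-likelihood in log-parameter space with
    moment-matching initialization.  Returns ``(k_hat, n_hat)``.
    """
    p = np.asarray(pvalues, dtype=float)
    if len(p) < 2:
        raise ValueError("need at least 2 values")
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("values must lie strictly in (0, 1)")
    m, v = p.mean(), p.var()
    v = max(v, 1e-12)
    common = max(m * (1 - m) / v - 1, 1e-3)
    k = max(m * common, 1e-3)
    nb = max((1 - m) * common, 1e-3)
    s1 = np.log(p).mean()
    s2 = np.log1p(-p).mean()
    theta = np.log([k, nb])
    for _ in range(max_iter):
        if not np.all(np.isfinite(theta)):
            break
        a, b = np.exp(theta)
        da = digamma(a + b) - digamma(a) + s1
        db = digamma(a + b) - digamma(b) + s2
        grad = np.array([a * da, b * db])
        tri_ab = polygamma(1, a + b)
        H = np.array(
            [
                [a * da + a * a * (tri_ab - polygamma(1, a)), a * b * tri_ab],
                [a * b * tri_ab, b * db + b * b * (tri_ab - polygamma(1, b))],
            ]
        )
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = grad / max(abs(np.diag(H)).max(), 1.0)
        step = np.clip(step, -2.0, 2.0)
        theta = theta - step
        if np.abs(step).max() < tol:
            a, b = np.exp(theta)
            return float(a), float(b)
    # Newton failed (degenerate minima distribution): constrained MLE fallback
    try:
        a, b, _, _ = stats.beta.fit(p, floc=0, fscale=1)
        if np.isfinite(a) and np.isfinite(b) and a > 0 and b > 0:
            return float(a), float(b)
    except Exception:
        pass
    raise RuntimeError(
        f"beta fit did not converge after {max_iter} iterations "
        f"(last params {np.exp(theta)})"
    )


def beta_loglik(pvalues: np.ndarray, k: float, n: float) -> float:
    return float(stats.beta.logpdf(pvalues, k, n).sum())


@dataclass
class PermutationResult:
    phenotype_id: str
    top_variant: str
    pval_nominal: float
    pval_empirical: float
    beta_k: float
    beta_n: float
    pval_beta: float
    n_permutations: int
    slope: float = np.nan
    slope_se: float = np.nan
    n_variants: int = 0


def permutation_pass(
    phenotype: np.ndarray,
    dosages: np.ndarray,
    covariates: np.ndarray | None,
    variant_ids,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    phenotype_id: str = "",
) -> PermutationResult:
    """Permutation correction across one cis window.

    The observed top nominal p is compared with the distribution of
    per-permutation minima: directly (empirical p) and through an MLE Beta
    fit (beta-adjusted p = Beta CDF of the observed top p).
    """
    if n_perm < 10:
        raise ValueError("need at least 10 permutations")
    if n_perm < 100:
        import warnings

        warnings.warn("fewer than 100 permutations: beta fit will be unstable")
    if rng is None:
        rng = np.random.default_rng()
    nom = nominal_scan(phenotype, dosages, covariates, variant_ids)
    top = int(np.argmax(nom["r2"].to_numpy()))
    dof = int(nom["dof"].iloc[0])
    yr = residualize(np.asarray(phenotype, float), covariates)
    Gr = residualize(np.asarray(dosages, float), covariates)
    norms = np.linalg.norm(Gr, axis=0)
    norms[norms == 0] = np.inf
    Gn = Gr / norms
    max_r2 = _perm_max_r2(yr, Gn, n_perm, rng)
    perm_min_p = _r2_to_pval(max_r2, dof)
    obs_p = float(nom["pval"].iloc[top])
    emp = (1.0 + np.sum(perm_min_p <= obs_p)) / (n_perm + 1.0)
    k_hat, n_hat = fit_beta_approx(np.clip(perm_min_p, 1e-300, 1 - 1e-12))
    adj = float(np.clip(betainc(k_hat, n_hat, obs_p), 1e-300, 1.0))
    return PermutationResult(
        phenotype_id=phenotype_id,
        top_variant=str(nom["variant"].iloc[top]) if "variant" in nom else str(top),
        pval_nominal=obs_p,
        pval_empirical=float(emp),
        beta_k=k_hat,
        beta_n=n_hat,
        pval_beta=adj,
        n_permutations=n_perm,
        slope=float(nom["slope"].iloc[top]),
        slope_se=float(nom["se"].iloc[top]),
        n_variants=dosages.shape[1] if np.ndim(dosages) == 2 else 1,
    )


def grouped_permutation_pass(
    phenotypes: np.ndarray,
    dosages: np.ndarray,
    covariates: np.ndarray | None,
    variant_ids,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    group_id: str = "",
    phenotype_ids=None,
) -> PermutationResult:
    """Permutation pass for a group of phenotypes sharing one correction.

    The observed statistic is the minimum nominal p over every
    (phenotype, variant) pair in the group; each permutation shuffles the
    samples once jointly for all group members, so the group-minimum null
    accounts for multiple junctions within the gene.
    """
    Y = np.atleast_2d(np.asarray(phenotypes, float))
    if Y.shape[0] == 0:
        raise ValueError("empty phenotype group")
    if Y.shape[1] != np.asarray(dosages).shape[0]:
        Y = Y.T if Y.shape[0] == np.asarray(dosages).shape[0] else Y
    if rng is None:
        rng = np.random.default_rng()
    n = Y.shape[1]
    c = 0 if covariates is None else np.atleast_2d(covariates).shape[1]
    dof = n - c - 2
    Gr = residualize(np.asarray(dosages, float), covariates)
    norms = np.linalg.norm(Gr, axis=0)
    norms[norms == 0] = np.inf
    Gn = Gr / norms
    Yr = residualize(Y.T, covariates).T  # groups x samples
    ynorms = np.linalg.norm(Yr, axis=1)
    best = (-1.0, 0, 0)
    for j in range(Yr.shape[0]):
        r = (Yr[j] @ Gn) / ynorms[j]
        v = int(np.argmax(r**2))
        if r[v] ** 2 > best[0]:
            best = (r[v] ** 2, j, v)
    obs_r2, jbest, vbest = best
    obs_p = float(_r2_to_pval(np.array([obs_r2]), dof)[0])

    perm_max = np.zeros(n_perm)
    # same construction as the single-phenotype pass so that identical
    # seeds yield identical permutations (group of one == plain pass)
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    for j in range(Yr.shape[0]):
        P = Yr[j][perms]
        R = (P @ Gn) / ynorms[j]
        perm_max = np.maximum(perm_max, (R**2).max(axis=1))
    perm_min_p = _r2_to_pval(perm_max, dof)
    emp = (1.0 + np.sum(perm_min_p <= obs_p)) / (n_perm + 1.0)
    k_hat, n_hat = fit_beta_approx(np.clip(perm_min_p, 1e-300, 1 - 1e-12))
    adj = float(np.clip(betainc(k_hat, n_hat, obs_p), 1e-300, 1.0))
    nom = nominal_scan(Y[jbest], dosages, covariates, variant_ids)
    pid = group_id
    if phenotype_ids is not None:
        pid = f"{phenotype_ids[jbest]}"
    return PermutationResult(
        phenotype_id=pid if pid else group_id,
        top_variant=str(nom["variant"].iloc[vbest]) if "variant" in nom else str(vbest),
        pval_nominal=obs_p,
        pval_empirical=float(emp),
        beta_k=k_hat,
        beta_n=n_hat,
        pval_beta=adj,
        n_permutations=n_perm,
        slope=float(nom["slope"].iloc[vbest]),
        slope_se=float(nom["se"].iloc[vbest]),
        n_variants=np.asarray(dosages).shape[1],
    )


# ---------------------------------------------------------------------------
# genome-wide FDR
# ---------------------------------------------------------------------------

def estimate_pi0(pvalues: np.ndarray, lambdas=None) -> float:
    """Storey pi0 via a cubic smoother over the lambda grid, evaluated at
    the largest lambda; falls back to 1 when unstable."""
    p = np.asarray(pvalues, float)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    pi0_l = np.array([(p > lam).mean() / (1 - lam) for lam in lambdas])
    if np.all(pi0_l == 0):
        return 1e-3
    try:
        coef = np.polyfit(lambdas, pi0_l, deg=3)
        pi0 = float(np.polyval(coef, lambdas[-1]))
    except Exception:
        pi0 = float(pi0_l[-1])
    if not np.isfinite(pi0) or pi0 > 1 or pi0 <= 0:
        pi0 = 1.0 if (not np.isfinite(pi0) or pi0 > 1) else max(pi0_l.min(), 1e-3)
    return min(pi0, 1.0)


def storey_qvalues(pvalues: np.ndarray) -> tuple[np.ndarray, float]:
    """Storey q-values; returns (q, pi0)."""
    p = np.asarray(pvalues, float)
    if len(p) == 0:
        raise ValueError("empty p-value vector")
    pi0 = estimate_pi0(p) if len(p) >= 100 else 1.0
    m = len(p)
    order = np.argsort(p)
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(q, 0, 1)
    return out, pi0


def gene_thresholds(
    perm_results: list[PermutationResult], fdr: float = 0.05
) -> pd.DataFrame:
    """Genome-wide FDR over beta-adjusted p-values and per-phenotype nominal
    thresholds.

    The adjusted-p significance boundary ``p*`` is the midpoint between the
    largest significant and the smallest non-significant adjusted p; each
    significant phenotype's nominal threshold is the Beta quantile of
    ``p*`` under its own (k, n) fit.
    """
    df = pd.DataFrame([vars(r) for r in perm_results])
    if df.empty:
        raise ValueError("no permutation results")
    q, pi0 = storey_qvalues(df["pval_beta"].to_numpy())
    df["qvalue"] = q
    sig = df["qvalue"] <= fdr
    if sig.any():
        p_sig_max = df.loc[sig, "pval_beta"].max()
        nonsig = df.loc[~sig, "pval_beta"]
        p_star = (
            (p_sig_max + nonsig.min()) / 2.0 if len(nonsig) else (p_sig_max + 1.0) / 2.0
        )
    else:
        p_star = np.nan
    thr = np.full(len(df), np.nan)
    if sig.any():
        thr[sig.to_numpy()] = stats.beta.ppf(
            p_star, df.loc[sig, "beta_k"], df.loc[sig, "beta_n"]
        )
    df["pval_nominal_threshold"] = thr
    df["significant"] = sig
    df.attrs["pi0"] = pi0
    df.attrs["p_star"] = p_star
    return df


# ---------------------------------------------------------------------------
# conditional pass
# ---------------------------------------------------------------------------

@dataclass
class IndependentSignal:
    phenotype_id: str
    rank: int
    top_variant: str
    pval: float
    members: list = field(default_factory=list)


def conditional_pass(
    phenotype: np.ndarray,
    dosages: np.ndarray,
    covariates: np.ndarray | None,
    variant_ids,
    positions: np.ndarray,
    threshold: float,
    phenotype_id: str = "",
    max_signals: int = 10,
) -> list[IndependentSignal]:
    """Forward/backward stepwise scan for independent cis signals.

    Forward: repeatedly add the best remaining variant to the covariates
    while its conditional p is below the phenotype's nominal threshold.
    Backward: rescan for each forward signal conditioning on the others'
    top variants; signals whose best conditional p stays below threshold
    are retained and re-ranked, and every significant variant is assigned
    to the signal under which it is most significant (tie: smaller
    position).
    """
    if not np.isfinite(threshold):
        raise ValueError("phenotype has no nominal threshold")
    y = np.asarray(phenotype, float)
    G = np.asarray(dosages, float)
    ids = np.asarray(variant_ids)
    pos = np.asarray(positions)
    base_cov = (
        np.empty((len(y), 0)) if covariates is None else np.atleast_2d(covariates)
    )

    forward: list[int] = []
    while len(forward) < max_signals:
        C = np.column_stack([base_cov] + [G[:, j] for j in forward]) if forward else base_cov
        nom = nominal_scan(y, G, C if C.size else None)
        pvals = nom["pval"].to_numpy().copy()
        pvals[forward] = 1.0
        best = int(np.argmin(pvals))
        if pvals[best] >= threshold:
            break
        forward.append(best)
    if not forward:
        return []

    retained = []
    for i, ji in enumerate(forward):
        others = [G[:, j] for k, j in enumerate(forward) if k != i]
        C = np.column_stack([base_cov] + others) if others else base_cov
        nom = nominal_scan(y, G, C if C.size else None)
        pv = nom["pval"].to_numpy().copy()
        for k, j in enumerate(forward):
            if k != i:
                pv[j] = 1.0
        best = int(np.argmin(pv))
        if pv[best] < threshold:
            retained.append((best, pv))
    if not retained:
        return []
    retained.sort(key=lambda t: (t[1][t[0]], pos[t[0]]))
    # assign each significant variant to its best signal
    assignment = {}
    for rank, (top, pv) in enumerate(retained, start=1):
        for v in np.nonzero(pv < threshold)[0]:
            cur = assignment.get(v)
            cand = (pv[v], pos[v], rank)
            if cur is None or (cand[0], cand[1]) < (cur[0], cur[1]):
                assignment[v] = (pv[v], pos[v], rank)
    signals = []
    for rank, (top, pv) in enumerate(retained, start=1):
        members = [ids[v] for v, a in assignment.items() if a[2] == rank]
        signals.append(
            IndependentSignal(
                phenotype_id=phenotype_id,
                rank=rank,
                top_variant=str(ids[top]),
                pval=float(pv[top]),
                members=sorted(members),
            )
        )
    return signals


# ---------------------------------------------------------------------------
# trans scan
# ---------------------------------------------------------------------------

def trans_scan(
    phenotypes: pd.DataFrame,
    anchors: pd.DataFrame,
    genotypes: GenotypeData,
    covariates: np.ndarray | None = None,
    min_distance: int = 5_000_000,
    min_maf: float = 0.05,
    n_perm: int = 100,
    fdr: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Scan variant-phenotype pairs beyond ``min_distance`` of the anchor.

    FDR by the permutation-rank method: the full scan is repeated on
    ``n_perm`` joint sample permutations, and the FDR at threshold t is the
    mean permuted count of p <= t over the observed count.
    """
    var = genotypes.variants
    keep = var["maf"].to_numpy() >= min_maf
    if "mappability" in var.columns:
        keep &= var["mappability"].to_numpy() >= 1.0
    G = genotypes.dosages[:, keep]
    vids = var["id"].to_numpy()[keep]
    vchrom = var["chrom"].to_numpy()[keep]
    vpos = var["pos"].to_numpy()[keep]

    Y = phenotypes.to_numpy(dtype=float)
    n = Y.shape[1]
    c = 0 if covariates is None else np.atleast_2d(covariates).shape[1]
    dof = n - c - 2
    Gr = residualize(G, covariates)
    norms = np.linalg.norm(Gr, axis=0)
    norms[norms == 0] = np.inf
    Gn = Gr / norms
    Yr = residualize(Y.T, covariates).T
    ynorm = np.linalg.norm(Yr, axis=1, keepdims=True)
    ynorm[ynorm == 0] = np.inf

    testable = np.ones((Y.shape[0], G.shape[1]), dtype=bool)
    for i, pid in enumerate(phenotypes.index):
        a = anchors.loc[pid]
        same = vchrom == a["chrom"]
        testable[i] = ~same | (np.abs(vpos - a["pos"]) > min_distance)

    R = (Yr / ynorm) @ Gn
    pv = _r2_to_pval(R**2, dof)
    obs_p = pv[testable]
    pairs = np.argwhere(testable)

    rng = np.random.default_rng(seed)
    perm_ps = []
    for _ in range(n_perm):
        idx = rng.permutation(n)
        Rp = (Yr[:, idx] / ynorm) @ Gn
        perm_ps.append(_r2_to_pval(Rp**2, dof)[testable])
    perm_sorted = np.sort(np.concatenate(perm_ps))

    order = np.argsort(obs_p)
    ranked = obs_p[order]
    # add-one smoothing: the observed scan counts as one extra permutation
    perm_count = (np.searchsorted(perm_sorted, ranked, side="right") + 1) / (
        n_perm + 1
    )
    fdr_at = perm_count / np.arange(1, len(ranked) + 1)
    fdr_mono = np.minimum.accumulate(fdr_at[::-1])[::-1]
    out = pd.DataFrame(
        {
            "phenotype": phenotypes.index.to_numpy()[pairs[order, 0]],
            "variant": vids[pairs[order, 1]],
            "pval": ranked,
            "fdr": np.clip(fdr_mono, 0, 1),
        }
    )
    out["significant"] = out["fdr"] < fdr
    return out


def trans_ld_filter(
    trans_hits: pd.DataFrame,
    cis_signal_variants: dict,
    genotypes: GenotypeData,
    r2_cut: float = 0.01,
) -> pd.DataFrame:
    """Drop a trans hit when its variant is in LD (r^2 > ``r2_cut``) with
    any cis signal variant of the same gene."""
    from .genotype import ld_r2

    dos = genotypes.dosages
    var_index = {v: j for j, v in enumerate(genotypes.variants["id"])}
    keep = []
    for _, row in trans_hits.iterrows():
        cis_vars = cis_signal_variants.get(row["phenotype"], [])
        drop = False
        for cv in cis_vars:
            if cv not in var_index or row["variant"] not in var_index:
                continue
            try:
                if ld_r2(dos[:, var_index[row["variant"]]], dos[:, var_index[cv]]) > r2_cut:
                    drop = True
                    break
            except ValueError:
                continue
        keep.append(not drop)
    return trans_hits[np.array(keep, dtype=bool)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# model / results wrappers
# ---------------------------------------------------------------------------

def anchors_from_bed(meta: pd.DataFrame, mode: str = "end") -> pd.DataFrame:
    """Phenotype anchors from a BED meta frame.

    ``mode='end'`` uses the interval end (TSS convention for expression,
    where the TSS is stored as a 1 bp interval); ``mode='start'`` uses
    start + 1 (intron-cluster start for splicing)."""
    pos = meta["end"] if mode == "end" else meta["start"] + 1
    return pd.DataFrame(
        {"chrom": meta["#chr"].to_numpy(), "pos": pos.to_numpy()},
        index=meta["pid"].to_numpy(),
    )


class CisQTLMapper:
    """Map cis molQTL for one tissue.

    Parameters
    ----------
    phenotypes : DataFrame (features x samples), normalized.
    anchors : DataFrame indexed by phenotype id with ``chrom``, ``pos``.
    genotypes : GenotypeData for the same samples (column order must match
        ``phenotypes.columns``).
    covariates : DataFrame (covariates x samples) or None.
    groups : optional Series mapping phenotype id -> group id; phenotypes
        sharing a group are permuted jointly and reported per group.
    """

    def __init__(
        self,
        phenotypes: pd.DataFrame,
        anchors: pd.DataFrame,
        genotypes: GenotypeData,
        covariates: pd.DataFrame | None = None,
        window: int = 1_000_000,
        min_maf: float = 0.01,
        groups: pd.Series | None = None,
    ):
        if list(phenotypes.columns) != list(genotypes.samples):
            raise ValueError("phenotype and genotype samples differ")
        self.phenotypes = phenotypes
        self.anchors = anchors
        self.genotypes = genotypes
        self.window = window
        self.min_maf = min_maf
        self.groups = groups
        self.covariates = covariates
        self._C = (
            covariates[phenotypes.columns].to_numpy(float).T
            if covariates is not None and len(covariates)
            else None
        )
        self._dosages = genotypes.dosages
        self._var = genotypes.variants

    def cis_window(self, pid: str):
        """Candidate variant indices for one phenotype's cis window."""
        a = self.anchors.loc[pid]
        var = self._var
        mask = (
            (var["chrom"].to_numpy() == a["chrom"])
            & (np.abs(var["pos"].to_numpy() - a["pos"]) <= self.window)
            & (var["maf"].to_numpy() >= self.min_maf)
        )
        return np.nonzero(mask)[0]

    def nominal(self, pid: str) -> pd.DataFrame:
        idx = self.cis_window(pid)
        y = self.phenotypes.loc[pid].to_numpy(float)
        return nominal_scan(
            y, self._dosages[:, idx], self._C, self._var["id"].to_numpy()[idx]
        )

    def fit(
        self, n_permutations: int = 1000, seed: int = 0, fdr: float = 0.05
    ) -> "CisQTLResults":
        results = []
        if self.groups is None:
            units = [(pid, [pid]) for pid in self.phenotypes.index]
        else:
            units = [
                (gid, list(members.index))
                for gid, members in self.groups.groupby(self.groups)
            ]
        for unit_id, members in units:
            # constant phenotypes (e.g. zeroed rows from normalization)
            # carry no signal and break the permutation null
            members = [
                m for m in members
                if np.ptp(self.phenotypes.loc[m].to_numpy(float)) > 0
            ]
            if not members:
                continue
            idx = self.cis_window(members[0])
            if len(idx) == 0:
                continue
            G = self._dosages[:, idx]
            vids = self._var["id"].to_numpy()[idx]
            rng = _pheno_seed(seed, unit_id)
            if len(members) == 1:
                res = permutation_pass(
                    self.phenotypes.loc[members[0]].to_numpy(float),
                    G,
                    self._C,
                    vids,
                    n_perm=n_permutations,
                    rng=rng,
                    phenotype_id=unit_id,
                )
            else:
                Y = self.phenotypes.loc[members].to_numpy(float)
                res = grouped_permutation_pass(
                    Y,
                    G,
                    self._C,
                    vids,
                    n_perm=n_permutations,
                    rng=rng,
                    group_id=unit_id,
                    phenotype_ids=members,
                )
                res.phenotype_id = unit_id
            results.append(res)
        table = gene_thresholds(results, fdr=fdr)
        return CisQTLResults(self, table, fdr=fdr)


class CisQTLResults:
    """Permutation-pass results with FDR, thresholds and conditional scan."""

    def __init__(self, model: CisQTLMapper, table: pd.DataFrame, fdr: float):
        self.model = model
        self.table = table
        self.fdr = fdr

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    @property
    def pi0(self) -> float:
        return self.table.attrs.get("pi0", np.nan)

    def threshold_for(self, pid: str) -> float:
        row = self.table[self.table["phenotype_id"] == pid]
        return float(row["pval_nominal_threshold"].iloc[0]) if len(row) else np.nan

    def conditional(self, max_signals: int = 10) -> pd.DataFrame:
        """Forward/backward conditional pass for all significant phenotypes.

        With grouped phenotypes the scan runs on the group's top phenotype.
        """
        rows = []
        for _, rec in self.significant.iterrows():
            unit = rec["phenotype_id"]
            pid = unit
            if pid not in self.model.phenotypes.index and self.model.groups is not None:
                members = self.model.groups[self.model.groups == unit].index
                best_p, pid = np.inf, members[0]
                for m in members:
                    nm = self.model.nominal(m)
                    if nm["pval"].min() < best_p:
                        best_p, pid = nm["pval"].min(), m
            idx = self.model.cis_window(pid)
            sigs = conditional_pass(
                self.model.phenotypes.loc[pid].to_numpy(float),
                self.model._dosages[:, idx],
                self.model._C,
                self.model._var["id"].to_numpy()[idx],
                self.model._var["pos"].to_numpy()[idx],
                rec["pval_nominal_threshold"],
                phenotype_id=unit,
                max_signals=max_signals,
            )
            for s in sigs:
                rows.append(
                    {
                        "phenotype_id": s.phenotype_id,
                        "rank": s.rank,
                        "top_variant": s.top_variant,
                        "pval": s.pval,
                        "n_members": len(s.members),
                        "members": ",".join(map(str, s.members)),
                    }
                )
        return pd.DataFrame(
            rows,
            columns=["phenotype_id", "rank", "top_variant", "pval", "n_members", "members"],
        )

    def summary(self) -> str:
        n = len(self.table)
        ns = int(self.table["significant"].sum())
        lines = [
            "cis-QTL permutation pass",
            "========================",
            f"phenotypes tested      {n}",
            f"significant (q<={self.fdr:g})  {ns}",
            f"pi0 estimate           {self.pi0:.3f}",
        ]
        if ns:
            top = self.significant.nsmallest(min(ns, 5), "pval_beta")
            lines.append("top associations:")
            for _, r in top.iterrows():
                lines.append(
                    f"  {r['phenotype_id']:>12} {r['top_variant']:>16} "
                    f"p_beta={r['pval_beta']:.3g} q={r['qvalue']:.3g} "
                    f"slope={r['slope']:+.3f}"
                )
        return "\n".join(lines)
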