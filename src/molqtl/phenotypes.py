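"""From raw counts to analysis-ready molecular phenotypes.

Expression: TPM, the expressed-gene filter (>=0.1 TPM and >=6 reads in
>=20% of samples), then across-sample quantile normalization followed by a
per-gene rank-based inverse normal transform.

Splicing: connected-component intron clustering over junctions sharing a
splice site, percent-spliced-in (PSI) within clusters, the three intron
filters (missingness > 50%, low variability, fewer than max(10, 0.1 n)
unique values), then per-junction standardization and inverse normal
transform.

Also: residual-PCA hidden-factor estimation (the role PEER plays in cohort
studies), tissue-enrichment classes and cross-tissue rank similarity.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm, spearmanr


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def compute_tpm(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million: ``(c_g / L_g) / sum_h (c_h / L_h) * 1e6``."""
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("all genes need a positive length")
    rate = counts.div(lengths, axis=0)
    denom = rate.sum(axis=0)
    if (denom <= 0).any():
        raise ValueError("sample with zero total expression")
    return rate.div(denom, axis=1) * 1e6


def filter_expressed_genes(
    counts: pd.DataFrame,
    tpm: pd.DataFrame,
    min_tpm: float = 0.1,
    min_reads: int = 6,
    min_fraction: float = 0.2,
) -> pd.Index:
    """Genes where >= ``min_fraction`` of samples have both >= ``min_tpm``
    TPM and >= ``min_reads`` reads (all thresholds inclusive)."""
    ok = (tpm >= min_tpm) & (counts >= min_reads)
    frac = ok.mean(axis=1)
    return counts.index[frac >= min_fraction]


def rank_inverse_normal(values: np.ndarray, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Blom rank-based inverse normal transform, ties averaged."""
    v = np.asarray(values, dtype=float)
    n = len(v)
    ranks = pd.Series(v).rank(method="average").to_numpy()
    return norm.ppf((ranks - offset) / (n + 1 - 2 * offset))


def quantile_normalize_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Map every column onto the mean sorted profile (ties averaged)."""
    arr = df.to_numpy(dtype=float)
    order = np.argsort(arr, axis=0)
    sorted_arr = np.take_along_axis(arr, order, axis=0)
    mean_profile = sorted_arr.mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        ranks = pd.Series(arr[:, j]).rank(method="average").to_numpy() - 1.0
        lo = np.floor(ranks).astype(int)
        hi = np.ceil(ranks).astype(int)
        out[:, j] = 0.5 * (mean_profile[lo] + mean_profile[hi])
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def normalize_expression(tpm: pd.DataFrame) -> pd.DataFrame:
    """Quantile normalization across samples, then per-gene inverse normal.

    Genes constant across samples (in the input) come back as rows of
    zeros with a warning; everything else gets mean ~0, variance ~1 by
    construction (exactly so for tie-free rows).
    """
    const_mask = np.ptp(tpm.to_numpy(), axis=1) == 0
    qn = quantile_normalize_columns(tpm)
    out = np.empty(qn.shape)
    arr = qn.to_numpy()
    for i in range(arr.shape[0]):
        if const_mask[i] or np.ptp(arr[i]) == 0:
            out[i] = 0.0
        else:
            out[i] = rank_inverse_normal(arr[i])
    if const_mask.any():
        warnings.warn(f"{const_mask.sum()} constant genes normalized to zeros")
    return pd.DataFrame(out, index=tpm.index, columns=tpm.columns)


# ---------------------------------------------------------------------------
# splicing
# ---------------------------------------------------------------------------

def cluster_introns(
    junctions: pd.DataFrame, gene_models: pd.DataFrame | None = None,
    min_fraction: float = 0.001,
) -> pd.DataFrame:
    """Group junctions into intron clusters by shared splice sites.

    Two junctions on the same chromosome and strand that share a donor or
    acceptor coordinate join one cluster (connected components); singleton
    components are discarded, and junctions carrying less than
    ``min_fraction`` of their cluster's reads are removed.  If
    ``gene_models`` is given (columns gene, chrom, tss, strand, length),
    each cluster is assigned to the gene whose span contains its start on
    the matching strand.

    ``junctions`` columns: chrom, start, end, strand, and optionally
    ``count`` (summed over samples) for the usage filter.
    """
    import networkx as nx

    if (junctions["start"] >= junctions["end"]).any():
        raise ValueError("junction start must be < end")
    jx = junctions.reset_index(drop=True)
    G = nx.Graph()
    G.add_nodes_from(jx.index)
    for _, grp in jx.groupby(["chrom", "strand"]):
        for site_col in ("start", "end"):
            for _, site_grp in grp.groupby(site_col):
                idx = site_grp.index.to_list()
                G.add_edges_from(zip(idx[:-1], idx[1:]))
    rows = []
    cid = 0
    for comp in sorted(nx.connected_components(G), key=lambda c: min(c)):
        if len(comp) < 2:
            continue
        members = jx.loc[sorted(comp)].copy()
        if "count" in members:
            total = members["count"].sum()
            if total > 0:
                members = members[members["count"] >= min_fraction * total]
            if len(members) < 2:
                continue
        cluster_id = f"clu_{cid}"
        cid += 1
        cluster_start = int(members["start"].min())
        gene = ""
        if gene_models is not None:
            span = gene_models[
                (gene_models["chrom"] == members["chrom"].iloc[0])
                & (gene_models["strand"] == members["strand"].iloc[0])
                & (gene_models["tss"] <= cluster_start)
                & (gene_models["tss"] + gene_models["length"] * 10 >= cluster_start)
            ]
            if len(span):
                gene = span.iloc[0]["gene"]
        members["cluster"] = cluster_id
        members["cluster_start"] = cluster_start
        members["gene"] = gene
        rows.append(members)
    if not rows:
        return pd.DataFrame(
            columns=list(jx.columns) + ["cluster", "cluster_start", "gene"]
        )
    return pd.concat(rows, ignore_index=True)


def compute_psi(counts: pd.DataFrame, clusters: pd.Series) -> pd.DataFrame:
    """Percent spliced-in: junction count over cluster total per sample;
    missing (NaN) where the cluster total is zero."""
    sizes = clusters.groupby(clusters).size()
    if (sizes < 2).any():
        raise ValueError("clusters need >= 2 junctions")
    totals = counts.groupby(clusters.reindex(counts.index)).transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = counts / totals
    return psi.where(totals > 0)


def filter_and_normalize_introns(
    psi: pd.DataFrame,
    max_missing: float = 0.5,
    min_sd: float = 0.005,
    min_unique: float | None = None,
) -> pd.DataFrame:
    """Apply the three intron filters, then standardize + inverse normal.

    Filters: junctions missing in more than ``max_missing`` of samples;
    junctions with PSI standard deviation below ``min_sd``; junctions with
    fewer than ``max(10, 0.1 n)`` unique values (``min_unique`` overrides
    the default).  Missing PSI values are mean-imputed per junction before
    normalization.
    """
    n = psi.shape[1]
    thr_unique = max(10.0, 0.1 * n) if min_unique is None else min_unique
    keep = []
    for j, row in psi.iterrows():
        if row.isna().mean() > max_missing:
            continue
        vals = row.dropna()
        if vals.std(ddof=1) < min_sd or np.isnan(vals.std(ddof=1)):
            continue
        if vals.nunique() < thr_unique:
            continue
        keep.append(j)
    sub = psi.loc[keep]
    filled = sub.apply(lambda r: r.fillna(r.mean()), axis=1)
    standardized = filled.sub(filled.mean(axis=1), axis=0).div(
        filled.std(axis=1, ddof=1), axis=0
    )
    out = np.vstack([rank_inverse_normal(standardized.loc[j].to_numpy()) for j in keep]) \
        if keep else np.empty((0, n))
    return pd.DataFrame(out, index=keep, columns=psi.columns)


# ---------------------------------------------------------------------------
# covariates / hidden factors
# ---------------------------------------------------------------------------

def estimate_hidden_factors(
    normalized: pd.DataFrame, k: int = 10, known_covariates: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Top-k principal components of the phenotype matrix after removing
    known covariates; the expression-confounder proxy.

    Returns per-sample factor scores with orthonormal columns.
    """
    n = normalized.shape[1]
    if k >= n:
        raise ValueError("k must be < n_samples")
    if k == 0:
        return pd.DataFrame(index=normalized.columns)
    X = normalized.to_numpy(dtype=float).T  # samples x features
    X = X - X.mean(axis=0)
    if known_covariates is not None and known_covariates.shape[0] > 0:
        C = known_covariates[normalized.columns].to_numpy(dtype=float).T
        C = np.column_stack([np.ones(n), C])
        X = X - C @ np.linalg.lstsq(C, X, rcond=None)[0]
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    return pd.DataFrame(
        U[:, :k], index=normalized.columns, columns=[f"factor{i+1}" for i in range(k)]
    ).T


def build_covariate_set(
    genotype_pcs: pd.DataFrame,
    hidden_factors: pd.DataFrame,
    known: pd.DataFrame,
) -> pd.DataFrame:
    """Stack genotype PCs, hidden factors and known covariates
    (rows = covariates, columns = samples); rejects constant covariates."""
    parts = [genotype_pcs.T, hidden_factors, known]
    cov = pd.concat([p for p in parts if len(p)], axis=0)
    if cov.isna().any().any():
        raise ValueError("covariates incomplete for some samples")
    if (cov.std(axis=1) == 0).any():
        raise ValueError("constant covariate")
    return cov


# ---------------------------------------------------------------------------
# tissue comparisons
# ---------------------------------------------------------------------------

def classify_tissue_enrichment(
    mean_tpm: pd.DataFrame, expressed: dict, fold: float = 50.0
) -> pd.Series:
    """Per-gene class: 'specific' (expressed in exactly one tissue),
    'highly_enriched' (expressed in more, but the top tissue mean is at
    least ``fold`` times every other tissue mean), else 'shared'.

    ``expressed`` maps tissue -> set of genes passing the expression filter.
    """
    if mean_tpm.shape[1] < 2:
        raise ValueError("need >= 2 tissues")
    out = {}
    for gene, row in mean_tpm.iterrows():
        tissues_expressed = [t for t in mean_tpm.columns if gene in expressed[t]]
        if len(tissues_expressed) == 0:
            out[gene] = "not_expressed"
            continue
        if len(tissues_expressed) == 1:
            out[gene] = "specific"
            continue
        vals = row.to_numpy(dtype=float)
        top = np.argmax(vals)
        others = np.delete(vals, top)
        out[gene] = "highly_enriched" if np.all(vals[top] >= fold * others) else "shared"
    return pd.Series(out, name="enrichment_class")


def tissue_similarity(
    matrix_a: pd.DataFrame, matrix_b: pd.DataFrame
) -> float:
    """Spearman correlation of per-feature means over shared features."""
    shared = matrix_a.index.intersection(matrix_b.index)
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared features")
    rho, _ = spearmanr(
        matrix_a.loc[shared].mean(axis=1), matrix_b.loc[shared].mean(axis=1)
    )
    return float(rho)
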