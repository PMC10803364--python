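"""Synthetic multi-tissue molQTL cohorts with planted ground truth.

The generator emulates the study design the pipeline targets: a cohort of
~100 males with expression and splicing phenotypes measured in three
reproductive tissues (testis, epididymis, vas deferens), plus a disjoint,
larger genotyped cohort with a standardized fertility phenotype.  Every
regulatory effect is planted explicitly — cis-eQTL parameterised as log2
allelic fold changes, sQTL as Dirichlet concentration shifts, GWAS QTL as
additive and/or recessive effects that may share their causal variant with a
molQTL — so each downstream stage can be scored against known truth.

Genotypes are phased haplotypes from a first-order Markov chain along the
chromosome whose adjacent-variant allele correlation decays as
``exp(-d / ld_decay_length)``; allele frequencies are drawn from
``maf_range`` through a latent AR(1) with the same decay so that linkage and
allele-frequency similarity vanish together.  Expression counts are
negative binomial around the allelic-fold-change mean model

    mu_ig = depth * base_g * ((2 - g_i) + g_i * 2**delta) / 2
            * exp(covariates + hidden factors),

splicing counts are Dirichlet-multinomial within intron clusters, and
haplotype-resolved counts follow the phase of the planted eVariant.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import GenotypeData

TISSUES = ("testis", "epididymis", "vas_deferens")


def _child_seed(seed: int, label: str) -> int:
    """Stable per-stream seed below 2**31 derived from (seed, label)."""
    h = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31 - 1)


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    The defaults are the study conditions the pipeline is exercised under:
    three tissues of 117/103/84 samples, a disjoint fertility cohort of
    2,000 genotyped individuals, and a desk-scale genome of 3,000 variants
    and 300 genes on one 30 Mb chromosome.
    """

    seed: int = 0
    n_samples_per_tissue: tuple = (117, 103, 84)
    n_gwas_samples: int = 2000
    n_variants: int = 3000
    n_genes: int = 300
    n_clusters: int = 100
    n_chromosomes: int = 1
    chromosome_length: int = 30_000_000
    ld_decay_length: float = 50_000.0
    maf_range: tuple = (0.05, 0.5)
    cis_window: int = 1_000_000
    # cis architecture
    prop_egenes: float = 0.3
    prop_secondary: float = 0.1          # fraction of eGenes with a 2nd signal
    prop_sclusters: float = 0.3
    afc_magnitude_range: tuple = (0.25, 2.0)
    prop_shared_tissue_effects: float = 0.6  # P(eQTL active in all tissues)
    sqtl_shift_per_allele: float = 2.0
    # counts / noise
    dispersion: float = 0.1
    depth_scale: float = 1.0
    base_log_mean: float = 4.0
    base_log_sd: float = 1.0
    junction_depth: float = 100.0
    ase_coverage: float = 100.0
    phase_error_rate: float = 0.0
    n_hidden_factors: int = 3
    hidden_loading_sd: float = 0.15
    covariate_effect_sd: float = 0.05
    # GWAS architecture
    n_gwas_qtl: int = 3
    pct_shared_causal: float = 0.5
    beta_add_range: tuple = (0.15, 0.3)
    beta_rec_range: tuple = (0.4, 0.8)
    h2_polygenic: float = 0.2
    n_background_loci: int = 500

    def validate(self) -> None:
        if self.n_variants < 2:
            raise ValueError("n_variants must be >= 2")
        lo, hi = self.maf_range
        if not (0 < lo < hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo < hi <= 0.5")
        for name in (
            "n_genes",
            "n_clusters",
            "n_gwas_samples",
            "chromosome_length",
            "cis_window",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(n <= 0 for n in self.n_samples_per_tissue):
            raise ValueError("sample sizes must be positive")
        if self.ld_decay_length < 0:
            raise ValueError("ld_decay_length must be >= 0")


@dataclass
class PlantedTruth:
    """Ground-truth effect tables for one simulated cohort.

    ``eqtl`` rows: gene, variant, afc (log2), tissues (comma list), rank.
    ``sqtl`` rows: cluster, gene, variant, log2_shift, tissues.
    ``gwas_qtl`` rows: variant, beta_add, beta_rec, shared_gene.
    """

    eqtl: pd.DataFrame
    sqtl: pd.DataFrame
    gwas_qtl: pd.DataFrame
    hidden_loadings: dict = field(default_factory=dict)
    covariate_effects: dict = field(default_factory=dict)

    def eqtl_for_tissue(self, tissue: str) -> pd.DataFrame:
        mask = self.eqtl["tissues"].str.split(",").apply(lambda t: tissue in t)
        return self.eqtl[mask]


@dataclass
class SimulatedCohort:
    """Complete synthetic data set: molQTL cohort + disjoint GWAS cohort."""

    config: SimConfig
    genotypes: GenotypeData                       # molQTL cohort (union of tissues)
    gene_models: pd.DataFrame
    tissue_samples: dict                          # tissue -> list of sample ids
    expression_counts: dict                       # tissue -> DataFrame genes x samples
    haplotype_counts: pd.DataFrame
    cluster_models: pd.DataFrame                  # one row per junction
    junction_counts: dict                         # tissue -> DataFrame junctions x samples
    covariates: pd.DataFrame                      # covariates x samples (age, rin)
    gwas_genotypes: GenotypeData
    gwas_phenotype: pd.Series
    truth: PlantedTruth


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_variant_frame(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Variant positions and allele frequencies.

    Frequencies come from a latent Gaussian AR(1) along each chromosome with
    correlation ``exp(-d / ld_decay_length)`` mapped uniformly onto
    ``maf_range``, so nearby variants have similar frequencies on the same
    length scale as their linkage.
    """
    from scipy.stats import norm

    per_chrom = np.full(config.n_chromosomes, config.n_variants // config.n_chromosomes)
    per_chrom[: config.n_variants % config.n_chromosomes] += 1
    frames = []
    for c, m in enumerate(per_chrom, start=1):
        pos = np.sort(
            rng.choice(
                np.arange(1, config.chromosome_length, dtype=np.int64),
                size=m,
                replace=False,
            )
        )
        d = np.diff(pos).astype(float)
        if config.ld_decay_length > 0:
            rho = np.exp(-d / config.ld_decay_length)
        else:
            rho = np.zeros_like(d)
        z = np.empty(m)
        z[0] = rng.standard_normal()
        eps = rng.standard_normal(m - 1) if m > 1 else np.empty(0)
        for v in range(1, m):
            z[v] = rho[v - 1] * z[v - 1] + np.sqrt(1 - rho[v - 1] ** 2) * eps[v - 1]
        lo, hi = config.maf_range
        p = lo + (hi - lo) * norm.cdf(z)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": f"chr{c}",
                    "pos": pos,
                    "id": [f"chr{c}:{x}" for x in pos],
                    "ref": "A",
                    "alt": "C",
                    "freq": p,
                    "rho_next": np.append(rho, 0.0),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _markov_haplotypes(
    variants: pd.DataFrame, n_haplotypes: int, rng: np.random.Generator
) -> np.ndarray:
    """Binary Markov chain haplotypes with exact Bernoulli(freq) marginals.

    Adjacent-variant correlation is ``rho_next`` clipped to the Frechet
    bounds that keep the transition probabilities in [0, 1].
    """
    p = variants["freq"].to_numpy()
    rho = variants["rho_next"].to_numpy()
    new_chrom = variants["chrom"].ne(variants["chrom"].shift()).to_numpy()
    m = len(p)
    hap = np.empty((n_haplotypes, m), dtype=np.int8)
    u = rng.random((n_haplotypes, m))
    hap[:, 0] = u[:, 0] < p[0]
    for v in range(1, m):
        if new_chrom[v]:
            hap[:, v] = u[:, v] < p[v]
            continue
        pp, pv = p[v - 1], p[v]
        r = rho[v - 1]
        bound = min(
            np.sqrt(pp * (1 - pv) / ((1 - pp) * pv)),
            np.sqrt((1 - pp) * pv / (pp * (1 - pv))),
        )
        r = min(r, bound)
        t11 = pv + r * np.sqrt((1 - pp) / pp * pv * (1 - pv))
        t01 = pv - r * np.sqrt(pp / (1 - pp) * pv * (1 - pv))
        prev = hap[:, v - 1] == 1
        thresh = np.where(prev, t11, t01)
        hap[:, v] = u[:, v] < thresh
    return hap


def simulate_genotypes(
    config: SimConfig,
    n_samples: int | None = None,
    variants: pd.DataFrame | None = None,
    seed_label: str = "genotypes",
) -> GenotypeData:
    """Phased LD-structured genotypes for ``n_samples`` individuals.

    Passing the ``variants`` frame of a previous call yields a second cohort
    genotyped at the same loci (same positions, frequencies and linkage
    process) but with independent individuals.
    """
    config.validate()
    rng = np.random.default_rng(_child_seed(config.seed, seed_label))
    if n_samples is None:
        n_samples = sum(config.n_samples_per_tissue)
    if variants is None:
        variants = simulate_variant_frame(config, rng)
    hap = _markov_haplotypes(variants, 2 * n_samples, rng)
    out = variants.drop(columns=["rho_next"], errors="ignore").copy()
    dos = hap[0::2].astype(float) + hap[1::2].astype(float)
    af = dos.mean(axis=0) / 2.0
    out["maf"] = np.minimum(af, 1 - af)
    samples = [f"{seed_label[:1].upper()}{i:04d}" for i in range(n_samples)]
    return GenotypeData(variants=out, haplotypes=hap, samples=samples)


# ---------------------------------------------------------------------------
# gene / cluster models and planted truth
# ---------------------------------------------------------------------------

def simulate_gene_models(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    per_chrom = np.full(config.n_chromosomes, config.n_genes // config.n_chromosomes)
    per_chrom[: config.n_genes % config.n_chromosomes] += 1
    rows = []
    g = 0
    for c, k in enumerate(per_chrom, start=1):
        tss = np.sort(rng.integers(1, config.chromosome_length, size=k))
        for t in tss:
            length = int(np.exp(rng.normal(8.0, 0.6)))  # ~1-10 kb
            strand = rng.choice(["+", "-"])
            rows.append(
                {
                    "gene": f"G{g:04d}",
                    "chrom": f"chr{c}",
                    "tss": int(t),
                    "strand": strand,
                    "length": length,
                    "n_exons": int(rng.integers(2, 15)),
                }
            )
            g += 1
    return pd.DataFrame(rows)


def _pick_cis_variant(
    gene_row, variants: pd.DataFrame, config: SimConfig, rng, exclude=()
):
    in_win = variants[
        (variants["chrom"] == gene_row["chrom"])
        & (np.abs(variants["pos"] - gene_row["tss"]) <= config.cis_window)
        & (~variants["id"].isin(exclude))
    ]
    if in_win.empty:
        return None
    return in_win.iloc[rng.integers(0, len(in_win))]["id"]


def _draw_tissue_mask(config: SimConfig, rng) -> str:
    if rng.random() < config.prop_shared_tissue_effects:
        return ",".join(TISSUES)
    k = rng.integers(1, len(TISSUES))
    idx = rng.choice(len(TISSUES), size=k, replace=False)
    return ",".join(TISSUES[i] for i in sorted(idx))


def plant_truth(
    config: SimConfig,
    variants: pd.DataFrame,
    gene_models: pd.DataFrame,
    cluster_models: pd.DataFrame,
    rng: np.random.Generator,
) -> PlantedTruth:
    """Draw the planted effect tables for one cohort."""
    lo, hi = config.afc_magnitude_range
    eqtl_rows = []
    for _, g in gene_models.iterrows():
        if rng.random() >= config.prop_egenes:
            continue
        vid = _pick_cis_variant(g, variants, config, rng)
        if vid is None:
            continue
        afc = rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])
        mask = _draw_tissue_mask(config, rng)
        eqtl_rows.append(
            {"gene": g["gene"], "variant": vid, "afc": afc, "tissues": mask, "rank": 1}
        )
        if rng.random() < config.prop_secondary:
            vid2 = _pick_cis_variant(g, variants, config, rng, exclude=[vid])
            if vid2 is not None:
                afc2 = rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])
                eqtl_rows.append(
                    {
                        "gene": g["gene"],
                        "variant": vid2,
                        "afc": afc2,
                        "tissues": mask,
                        "rank": 2,
                    }
                )
    eqtl = pd.DataFrame(
        eqtl_rows, columns=["gene", "variant", "afc", "tissues", "rank"]
    )

    sqtl_rows = []
    for cid, grp in cluster_models.groupby("cluster", sort=True):
        if rng.random() >= config.prop_sclusters:
            continue
        g = gene_models[gene_models["gene"] == grp["gene"].iloc[0]].iloc[0]
        vid = _pick_cis_variant(g, variants, config, rng)
        if vid is None:
            continue
        sqtl_rows.append(
            {
                "cluster": cid,
                "gene": g["gene"],
                "variant": vid,
                "log2_shift": np.log2(config.sqtl_shift_per_allele),
                "tissues": _draw_tissue_mask(config, rng),
            }
        )
    sqtl = pd.DataFrame(
        sqtl_rows, columns=["cluster", "gene", "variant", "log2_shift", "tissues"]
    )

    gwas_rows = []
    shared_pool = eqtl[eqtl["rank"] == 1]
    n_shared = int(round(config.pct_shared_causal * config.n_gwas_qtl))
    chosen = set()
    for q in range(config.n_gwas_qtl):
        if q < n_shared and len(shared_pool) > 0:
            row = shared_pool.iloc[rng.integers(0, len(shared_pool))]
            vid, shared_gene = row["variant"], row["gene"]
        else:
            vid = variants.iloc[rng.integers(0, len(variants))]["id"]
            shared_gene = ""
        if vid in chosen:
            continue
        chosen.add(vid)
        recessive = rng.random() < 0.5
        gwas_rows.append(
            {
                "variant": vid,
                "beta_add": 0.0 if recessive else rng.uniform(*config.beta_add_range),
                "beta_rec": rng.uniform(*config.beta_rec_range) if recessive else 0.0,
                "shared_gene": shared_gene,
            }
        )
    gwas_qtl = pd.DataFrame(
        gwas_rows, columns=["variant", "beta_add", "beta_rec", "shared_gene"]
    )

    n_genes = len(gene_models)
    loadings = {
        t: rng.normal(0.0, config.hidden_loading_sd, size=(config.n_hidden_factors, n_genes))
        for t in TISSUES
    }
    cov_eff = {
        "age": rng.normal(0.0, config.covariate_effect_sd, size=n_genes),
        "rin": rng.normal(0.0, config.covariate_effect_sd, size=n_genes),
    }
    return PlantedTruth(
        eqtl=eqtl,
        sqtl=sqtl,
        gwas_qtl=gwas_qtl,
        hidden_loadings=loadings,
        covariate_effects=cov_eff,
    )


def simulate_cluster_models(
    config: SimConfig, gene_models: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Intron clusters: junctions sharing a donor site inside host genes."""
    rows = []
    hosts = gene_models.iloc[: config.n_clusters]
    for k, (_, g) in enumerate(hosts.iterrows()):
        n_j = int(rng.integers(2, 5))
        start = g["tss"] + int(rng.integers(100, 2000))
        ends = start + np.sort(rng.choice(np.arange(500, 8000), n_j, replace=False))
        for j, e in enumerate(ends):
            rows.append(
                {
                    "cluster": f"clu_{k:03d}",
                    "junction": f"clu_{k:03d}:J{j}",
                    "gene": g["gene"],
                    "chrom": g["chrom"],
                    "start": start,
                    "end": int(e),
                    "strand": g["strand"],
                    "alpha": rng.uniform(1.0, 5.0),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# molecular phenotypes
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float):
    """Gamma-Poisson negative binomial with var = mu + dispersion * mu^2."""
    mean = np.maximum(mean, 1e-12)
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean / shape)
    return rng.poisson(lam)


def afc_dosage_factor(dosage: np.ndarray, delta: float) -> np.ndarray:
    """Mean scaling of expression under a cis log2 fold change ``delta``:
    ``((2 - g) + g * 2**delta) / 2`` for dosage g in {0, 1, 2}."""
    return ((2.0 - dosage) + dosage * 2.0**delta) / 2.0


def simulate_expression(
    genotypes: GenotypeData,
    gene_models: pd.DataFrame,
    truth: PlantedTruth,
    config: SimConfig,
    tissue_samples: dict,
    covariates: pd.DataFrame,
    rng: np.random.Generator,
) -> dict:
    """Negative-binomial expression counts per tissue.

    The cis term multiplies the gene's base rate by the allelic-fold-change
    factor of each planted eQTL active in the tissue; covariates and hidden
    factors act multiplicatively on the log scale.
    """
    missing = set(truth.eqtl["variant"]) - set(genotypes.variants["id"])
    if missing:
        raise ValueError(f"planted variants absent from genotypes: {sorted(missing)[:3]}")
    var_index = {v: j for j, v in enumerate(genotypes.variants["id"])}
    sample_index = {s: i for i, s in enumerate(genotypes.samples)}
    dosages = genotypes.dosages
    base = np.exp(
        rng.normal(config.base_log_mean, config.base_log_sd, size=len(gene_models))
    )
    out = {}
    for t, samples in tissue_samples.items():
        idx = np.array([sample_index[s] for s in samples])
        n = len(idx)
        factors = rng.standard_normal((n, config.n_hidden_factors))
        eta = factors @ truth.hidden_loadings[t]
        for cov_name, eff in truth.covariate_effects.items():
            cv = covariates.loc[cov_name, samples].to_numpy(float)
            eta += np.outer(cv, eff)
        mu = config.depth_scale * base[None, :] * np.exp(eta)
        active = truth.eqtl_for_tissue(t)
        for _, e in active.iterrows():
            gidx = gene_models.index[gene_models["gene"] == e["gene"]][0]
            g = dosages[idx, var_index[e["variant"]]]
            mu[:, gidx] = mu[:, gidx] * afc_dosage_factor(g, e["afc"])
        counts = _nb_draw(rng, mu, config.dispersion)
        out[t] = pd.DataFrame(
            counts.T, index=gene_models["gene"].to_numpy(), columns=samples
        )
    return out


def simulate_haplotype_counts(
    genotypes: GenotypeData,
    truth: PlantedTruth,
    config: SimConfig,
    tissue_samples: dict,
    rng: np.random.Generator,
    tissue: str = TISSUES[0],
) -> pd.DataFrame:
    """Haplotype-resolved read counts for planted eGenes.

    The gene's allele-informative expression level is drawn once per sample
    from a gamma with the configured dispersion; the two haplotype counts
    are then Poisson around that level split in ratio ``2**afc``
    (alt-linked : ref-linked) for heterozygotes at the top eVariant.  Each
    count is marginally negative binomial, but the biological noise is
    shared between the haplotypes and cancels from their ratio, so
    homozygotes (split symmetrically with arbitrary haplotype labels) show
    only Poisson-level imbalance.  ``phase_error_rate`` swaps the allele
    linkage of a heterozygote with the given probability.
    """
    var_index = {v: j for j, v in enumerate(genotypes.variants["id"])}
    sample_index = {s: i for i, s in enumerate(genotypes.samples)}
    hap = genotypes.haplotypes
    rows = []
    top = truth.eqtl[truth.eqtl["rank"] == 1]
    for _, e in top.iterrows():
        if tissue not in e["tissues"].split(","):
            continue
        j = var_index[e["variant"]]
        ratio = 2.0 ** e["afc"]
        for s in tissue_samples[tissue]:
            i = sample_index[s]
            a, b = hap[2 * i, j], hap[2 * i + 1, j]
            g = int(a + b)
            frac_alt = ratio / (1 + ratio) if g == 1 else 0.5
            if config.dispersion > 0:
                shape = 1.0 / config.dispersion
                level = rng.gamma(shape, config.ase_coverage / shape)
            else:
                level = config.ase_coverage
            alt = int(rng.poisson(level * frac_alt))
            ref = int(rng.poisson(level * (1 - frac_alt)))
            if g == 1 and config.phase_error_rate > 0 and rng.random() < config.phase_error_rate:
                alt, ref = ref, alt
            rows.append(
                {
                    "gene": e["gene"],
                    "variant": e["variant"],
                    "sample": s,
                    "genotype": g,
                    "alt_count": alt,
                    "ref_count": ref,
                    "total": alt + ref,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["gene", "variant", "sample", "genotype", "alt_count", "ref_count", "total"],
    )


def simulate_junction_counts(
    genotypes: GenotypeData,
    cluster_models: pd.DataFrame,
    truth: PlantedTruth,
    config: SimConfig,
    tissue_samples: dict,
    rng: np.random.Generator,
) -> dict:
    """Dirichlet-multinomial junction counts per intron cluster and tissue.

    A planted sQTL multiplies the first junction's Dirichlet concentration
    by ``2**log2_shift`` per alternative allele at the sVariant.
    """
    sizes = cluster_models.groupby("cluster")["junction"].count()
    if (sizes < 2).any():
        raise ValueError("every intron cluster needs >= 2 junctions")
    var_index = {v: j for j, v in enumerate(genotypes.variants["id"])}
    sample_index = {s: i for i, s in enumerate(genotypes.samples)}
    dosages = genotypes.dosages
    sqtl_by_cluster = {r["cluster"]: r for _, r in truth.sqtl.iterrows()}
    out = {}
    for t, samples in tissue_samples.items():
        idx = np.array([sample_index[s] for s in samples])
        n = len(idx)
        mats = []
        jnames = []
        for cid, grp in cluster_models.groupby("cluster", sort=True):
            alpha0 = grp["alpha"].to_numpy()
            alpha = np.tile(alpha0, (n, 1))
            srow = sqtl_by_cluster.get(cid)
            if srow is not None and t in srow["tissues"].split(","):
                g = dosages[idx, var_index[srow["variant"]]]
                alpha[:, 0] *= (2.0 ** srow["log2_shift"]) ** g
            totals = _nb_draw(
                rng, np.full(n, config.junction_depth), config.dispersion
            )
            gam = rng.gamma(alpha)
            prob = gam / gam.sum(axis=1, keepdims=True)
            counts = np.vstack(
                [rng.multinomial(totals[i], prob[i]) for i in range(n)]
            )
            mats.append(counts.T)
            jnames.extend(grp["junction"].tolist())
        out[t] = pd.DataFrame(np.vstack(mats), index=jnames, columns=samples)
    return out


# ---------------------------------------------------------------------------
# GWAS cohort
# ---------------------------------------------------------------------------

def simulate_fertility_cohort(
    config: SimConfig,
    truth: PlantedTruth,
    variants: pd.DataFrame,
) -> tuple[GenotypeData, pd.Series]:
    """Disjoint genotyped cohort with a standardized fertility phenotype.

    ``y = sum beta_add * g + sum beta_rec * 1{g = 2} + u + e`` with a
    polygenic term ``u`` realised through ``n_background_loci`` random small
    effects (so the trait is genuinely heritable under the cohort's GRM),
    then standardized to zero mean and unit variance.
    """
    if len(truth.gwas_qtl) == 0:
        raise ValueError("truth contains no GWAS QTL")
    geno = simulate_genotypes(
        config, n_samples=config.n_gwas_samples, variants=variants, seed_label="gwas"
    )
    rng = np.random.default_rng(_child_seed(config.seed, "fertility"))
    dos = geno.dosages
    var_index = {v: j for j, v in enumerate(geno.variants["id"])}
    y = np.zeros(config.n_gwas_samples)
    for _, q in truth.gwas_qtl.iterrows():
        g = dos[:, var_index[q["variant"]]]
        y += q["beta_add"] * g + q["beta_rec"] * (g == 2.0)
    if config.h2_polygenic > 0 and config.n_background_loci > 0:
        bg = rng.choice(
            dos.shape[1], size=min(config.n_background_loci, dos.shape[1]), replace=False
        )
        X = dos[:, bg]
        X = (X - X.mean(axis=0)) / np.maximum(X.std(axis=0), 1e-9)
        b = rng.normal(0.0, np.sqrt(config.h2_polygenic / len(bg)), size=len(bg))
        y += X @ b
        sigma_e = np.sqrt(1.0 - config.h2_polygenic)
    else:
        sigma_e = 1.0
    y += rng.normal(0.0, sigma_e, size=config.n_gwas_samples)
    y = (y - y.mean()) / y.std()
    return geno, pd.Series(y, index=geno.samples, name="fertility")


# ---------------------------------------------------------------------------
# cohort assembly and persistence
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate the full molQTL + GWAS data set. Deterministic given seed."""
    config.validate()
    rng = np.random.default_rng(_child_seed(config.seed, "cohort"))
    frame_rng = np.random.default_rng(_child_seed(config.seed, "genotypes"))
    variant_frame = simulate_variant_frame(config, frame_rng)
    genotypes = simulate_genotypes(config, variants=variant_frame, seed_label="mol")
    gene_models = simulate_gene_models(config, rng)
    cluster_models = simulate_cluster_models(config, gene_models, rng)
    truth = plant_truth(config, genotypes.variants, gene_models, cluster_models, rng)

    samples = genotypes.samples
    tissue_samples = {}
    # overlapping membership: every sample has the first tissue by default,
    # later tissues take prefixes — mirrors one animal donating several tissues
    offsets = np.cumsum((0,) + tuple(config.n_samples_per_tissue))
    n_total = len(samples)
    for k, t in enumerate(TISSUES):
        n_t = config.n_samples_per_tissue[k]
        idx = [(offsets[k] + i) % n_total for i in range(n_t)]
        tissue_samples[t] = [samples[i] for i in sorted(set(idx))]

    cov = pd.DataFrame(
        {
            s: {
                "age": rng.uniform(1.0, 3.0),
                "rin": rng.uniform(6.0, 10.0),
            }
            for s in samples
        }
    )
    cov.loc["age"] = (cov.loc["age"] - cov.loc["age"].mean()) / cov.loc["age"].std()
    cov.loc["rin"] = (cov.loc["rin"] - cov.loc["rin"].mean()) / cov.loc["rin"].std()

    expr = simulate_expression(
        genotypes, gene_models, truth, config, tissue_samples, cov, rng
    )
    hap_counts = simulate_haplotype_counts(
        genotypes, truth, config, tissue_samples, rng
    )
    junc = simulate_junction_counts(
        genotypes, cluster_models, truth, config, tissue_samples, rng
    )
    gwas_geno, gwas_pheno = simulate_fertility_cohort(config, truth, variant_frame)
    assert not set(gwas_geno.samples) & set(samples), "cohorts must be disjoint"
    return SimulatedCohort(
        config=config,
        genotypes=genotypes,
        gene_models=gene_models,
        tissue_samples=tissue_samples,
        expression_counts=expr,
        haplotype_counts=hap_counts,
        cluster_models=cluster_models,
        junction_counts=junc,
        covariates=cov,
        gwas_genotypes=gwas_geno,
        gwas_phenotype=gwas_pheno,
        truth=truth,
    )


def expression_bed_frames(cohort: SimulatedCohort, tissue: str):
    """Phenotype BED (meta, values) for one tissue's expression counts."""
    gm = cohort.gene_models
    meta = pd.DataFrame(
        {
            "#chr": gm["chrom"],
            "start": gm["tss"] - 1,
            "end": gm["tss"],
            "pid": gm["gene"],
            "gid": gm["gene"],
            "strand": gm["strand"],
        }
    )
    return meta, cohort.expression_counts[tissue].reset_index(drop=True)


def junction_bed_frames(cohort: SimulatedCohort, tissue: str):
    cm = cohort.cluster_models
    meta = pd.DataFrame(
        {
            "#chr": cm["chrom"],
            "start": cm["start"],
            "end": cm["end"],
            "pid": cm["junction"],
            "gid": cm["gene"],
            "strand": cm["strand"],
        }
    )
    return meta, cohort.junction_counts[tissue].reset_index(drop=True)


def write_cohort(cohort: SimulatedCohort, directory: str) -> dict:
    """Write the cohort to ``directory``; returns a name -> path map."""
    import os

    from . import io as mio

    os.makedirs(directory, exist_ok=True)
    paths = {}

    def p(name):
        paths[name] = os.path.join(directory, name)
        return paths[name]

    mio.write_vcf(cohort.genotypes, p("molqtl.vcf"))
    mio.write_vcf(cohort.gwas_genotypes, p("gwas.vcf"))
    for t in cohort.expression_counts:
        meta, vals = expression_bed_frames(cohort, t)
        mio.write_phenotype_bed(meta, vals, p(f"expression_{t}.bed"))
        metaj, valsj = junction_bed_frames(cohort, t)
        mio.write_phenotype_bed(metaj, valsj, p(f"junctions_{t}.bed"))
    mio.write_covariates(cohort.covariates, p("covariates.tsv"))
    gwas = pd.DataFrame(
        {"sample": cohort.gwas_phenotype.index, "fertility": cohort.gwas_phenotype.values}
    )
    mio.write_table(gwas, p("gwas_phenotype.tsv"))
    mio.write_table(cohort.haplotype_counts, p("haplotype_counts.tsv"))
    mio.write_table(cohort.truth.eqtl, p("truth_eqtl.tsv"))
    mio.write_table(cohort.truth.sqtl, p("truth_sqtl.tsv"))
    mio.write_table(cohort.truth.gwas_qtl, p("truth_gwas_qtl.tsv"))
    mio.write_table(cohort.gene_models, p("gene_models.tsv"))
    mio.write_table(cohort.cluster_models, p("cluster_models.tsv"))
    return paths
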