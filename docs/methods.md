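# Methods

This note documents the statistical procedures, the synthetic-cohort
generator they are validated against, the numerical choices, and the known
limitations.

## Study design the package implements

The pipeline targets a multi-tissue molQTL study design: a cohort of
~100 genotyped males with bulk transcriptomes of testis, epididymis and
vas deferens (defaults 117/103/84 samples), and a second, disjoint cohort
of genotyped males (default 2,000 here; such cohorts are typically a few
thousand) with a standardized fertility phenotype but no transcriptomes.
Molecular phenotypes are mapped to cis variants, effect sizes are
expressed as allelic fold changes and validated through haplotype-level
allelic imbalance, effects are compared across tissues, and the fertility
GWAS is integrated with the molQTL resource through summary-statistic TWAS
and colocalization.

## cis mapping

Phenotypes and dosages are residualized on the covariates (with an
intercept), then each variant in the window (anchor ± 1 Mb, MAF ≥ 1%) is
tested by simple regression of the residuals. The t-test uses
`dof = n − c − 2`, which makes the slope, standard error and p-value
identical to the full-design least-squares fit (verified to 1e-8 in the
tests); the effective-dof learning of some mapping tools is not
reimplemented, since the downstream beta fit absorbs residual
miscalibration of the null.

**Permutation correction.** The residualized phenotype is permuted
(default 1,000 times) against fixed genotypes and covariates, and the
minimum p per permutation is recorded. The empirical p is
`(1 + #{perm ≤ obs}) / (N + 1)`. A Beta(k, n) distribution is fitted to
the permutation minima by maximum likelihood — Newton iteration on the
log-likelihood in log-parameter space from a moment-matching start, with
a constrained scipy MLE as fallback for degenerate minima distributions —
and the beta-adjusted p is the Beta CDF at the observed minimum. Grouped
phenotypes (all junctions of one gene) are permuted with a single sample
shuffle per permutation and summarised by the group minimum, so the
adjusted p accounts for the number of junctions within the gene.

**Genome-wide FDR.** Storey q-values over the adjusted p-values, with
pi0 from a cubic smoother over the lambda grid 0.05–0.95 (fallback 1 when
unstable, and pi0 = 1 for fewer than 100 phenotypes). The significance
boundary p\* is the midpoint between the largest significant and smallest
non-significant adjusted p; each significant phenotype's nominal
threshold is the Beta quantile of p\* under its own (k, n), which makes
"variants below the threshold" coincide exactly with the FDR set (tested
as a set-equality property).

**Conditional pass.** Forward: iteratively add the best variant to the
covariates while its conditional p is below the phenotype's nominal
threshold. Backward: rescan for each forward signal conditioning on the
other signals' top variants; retained signals are re-ranked by conditional
p, and each significant variant is assigned to the signal under which it
is most significant (ties to the smaller position).

**Trans scan.** All pairs beyond 5 Mb of the anchor (or on another
chromosome), variants at MAF ≥ 5%, with an optional mappability column
honoured as a pass-through filter. FDR is the permutation-rank estimate:
the full scan is repeated on (default 100) joint sample permutations and
the FDR at threshold t is the mean permuted count at t over the observed
count, with add-one smoothing (the observed scan counts as one more
permutation) and right-to-left monotonization. This estimator has an
irreducible per-dataset false-call probability of about 1/(N+1) — the
event that the observed minimum beats every permutation — which is why
null calibration is asserted over many seeds rather than per seed. Trans
hits in LD (r² > 0.01) with any cis signal variant of the same gene are
removed.

## Allelic fold change and imbalance

`estimate_afc` fits delta in the mean model
`E[expr | g] ∝ ((2 − g) + g·2^delta)/2` to size-factor-normalized
(median-of-ratios), log2(x+1)-transformed counts, by bounded 1-D
optimization of the profiled Gaussian likelihood (the linear nuisance part
is solved exactly at each delta); estimates are clamped to
|delta| ≤ log2(100). The +1 offset biases the estimate towards zero for
genes with counts of order 1–10; at typical coverage the bias is
negligible, and the recovery criterion (MAE < 0.2 for delta up to 2 at
n = 100) is met with margin.

`individual_log_afc` computes `log2((alt + 0.5)/(ref + 0.5))` per sample
from haplotype-resolved counts (coverage ≥ 8 reads), and the imbalance
test compares |log2 ratio| of heterozygotes vs homozygotes at the top
eVariant (≥10 each) by Wilcoxon rank-sum, using the exact small-sample
distribution when scipy's switch allows it, with Benjamini–Hochberg FDR
across genes. Absolute values are compared because the haplotype labels of
homozygotes are arbitrary; a `signed=True` flag exposes the signed
comparison. Phase comes from the simulator's truth; a `phase_error_rate`
parameter exists to probe robustness to phasing mistakes.

## Multi-tissue sharing

Effects of one top variant per gene (the cross-tissue maximum |z|,
ties to the smaller position, never mixing variants within a row) are
modeled as a mixture of zero-mean multivariate normals over tissues. The
covariance dictionary is fixed: identity, per-tissue singletons, the
all-ones equal-shared matrix, and one rank-1 component from the top
eigenvector of the strong-subset z-score covariance; the scale grid is
{0.1, 0.25, 0.5, 1, 2, 4}² × median(Ŝ²), plus a near-null component at
1e-8 × median(Ŝ²) so the point-mass limit is handled smoothly by the same
formulas. Mixture weights are fitted by EM (weights only; the dictionary
is fixed), asserting monotone log-likelihood, on the random background
subset (default 200,000 pairs or all available). Posteriors per pair mix
the per-component conditional normals; lfsr = min(P(b ≤ 0), P(b ≥ 0)).
The full data-driven covariance estimation of mash is deliberately not
reproduced; the fixed dictionary preserves the sharing/specificity
inference at desk scale and is documented as a simplification.

## GWAS

REML variance components by a single eigendecomposition of the GRM and
bounded 1-D optimization of the restricted likelihood over
log lambda ∈ [−5, 5]·ln 10; lambda below 2e-5 collapses to OLS. Per-variant
tests are GLS Wald tests in the rotated basis with components fixed at
the null estimates (EMMAX approximation; equivalence with explicit GLS
verified to 1e-6 on small panels). The GRM is the allele-frequency
standardized estimator; with sample-estimated frequencies its off-diagonal
mean is structurally −1/(n−1), which matters for interpreting
"unrelated" panels at small n.

M1/M2 recessive codings follow the binary definitions (hom-ref = 1 /
hom-alt = 1); eligibility requires MAF > 0.5% and coding frequency within
[0.005, 0.95] (the upper bound read as 95%, since a 0.95% upper bound
would leave the band almost empty; both ends are config-exposed). The
min-p statistic is reported without a two-test correction; its null
inflation (lambda_GC ≈ 2.3, consistent with the minimum of two weakly
correlated tests) is computed and emitted with every scan so downstream
consumers see it. Peaks merge significant variants (p < 5e-08) within
1 Mb; conditional scans add the conditioning variants' coded genotypes
(winning coding by default) as fixed covariates.

## TWAS and colocalization

Elastic-net models (mixing 0.5) are trained on covariate-residualized
phenotypes against cis dosages; the penalty is chosen by inner
cross-validation and performance by an outer K-fold split: rho_avg is the
mean out-of-fold Spearman correlation and zscore_pval a one-sided
Stouffer combination of per-fold Fisher-z scores. Note that a predictor
built from a single variant takes only three values, which tie-limits the
Spearman correlation to ≈0.85 even for a noiseless phenotype — relevant
when interpreting rho_avg for low-complexity models. High-performance
models require zscore_pval < 0.05 and rho_avg > 0.1 (strict).

The summary-statistic association is
`Z_g = Σ w_l (σ_l/σ_g)(β̂_l/se_l)` with `σ_g² = wᵀΓw` from the
model-training cohort (its own LD is the reference); model variants
missing from the GWAS statistics are dropped with a warning when >20% of
weight mass is lost. Colocalization uses Wakefield log-ABFs with prior
effect sd 0.15 on the standardized scale for both traits and priors
p1 = p2 = 1e-4, p12 = 1e-5; hypothesis sums run in log space, with
`H3 = H1·H2 − H4` evaluated by signed log-sum-exp. The cascade: TWAS on
high-performance models → per-modality Bonferroni → a secondary Bonferroni
at 0.05 over the count surviving the first → coloc within ±5 Mb of each
GWAS peak → retain PP.H4 > 0.8 and PP.H3 < 0.5. Splicing results are
reported at gene level as the best cluster per gene with cluster-count
Bonferroni.

## The synthetic cohort generator

**Genotypes.** Phased haplotypes from a first-order binary Markov chain
with exact Bernoulli(p_v) marginals and adjacent-variant correlation
`exp(−d/L)` (default L = 50 kb), clipped to the Fréchet-feasible range.
Allele frequencies are drawn from `maf_range` through a latent Gaussian
AR(1) with the same decay, so nearby variants have similar frequencies on
the same length scale as their linkage; this makes the full-linkage limit
attain r² → 1, which independent per-variant frequencies cannot. The
GWAS cohort is generated at the same loci (same frequency/linkage
process) with fresh individuals, so the two cohorts share variants but no
samples.

**Expression.** Negative-binomial counts (gamma–Poisson, gene dispersion
0.1; no noise model is prescribed by the design, so this standard RNA-seq
choice is ours) around
`depth · base_g · ((2−g) + g·2^delta)/2 · exp(covariates + hidden factors)`.
Hidden confounders are Gaussian factors with Gaussian loadings — the
structure residual-PCA (the PEER stand-in) is designed to absorb. Planted
cis effects have |delta| ∈ [0.25, 2] (config-exposed; the empirical
effect-size distribution of real cohorts is not calibrated here), tissue
masks with 60% fully shared, and optional secondary independent signals.

**Splicing.** Intron clusters of 2–4 junctions sharing a donor site;
junction counts are Dirichlet-multinomial around base concentrations, and
a planted sQTL multiplies the first junction's concentration by
2^shift per alternative allele.

**Haplotype counts.** The gene's allele-informative level is drawn once
per sample from a gamma (shared biological noise), then split Poisson
between haplotypes in ratio 2^delta for heterozygotes and symmetrically
for homozygotes. Marginally each count is negative binomial, but the
shared level cancels from the ratio, so homozygote imbalance is
Poisson-limited (median |log2 ratio| ≈ 0.09 at 500× coverage) — an
independent NB pair would violate that behaviour at any realistic
dispersion.

**Fertility phenotype.** `y = Σ β_add·g + Σ β_rec·1{g=2} + u + e`, with
the polygenic term realized through 500 random background loci (so the
trait is genuinely heritable under the cohort's own GRM, default
h² = 0.2), then standardized. A configurable fraction of GWAS QTL
(default 50%) reuses a planted eQTL's variant, the ground truth for
colocalization.

**What the generator does not emulate:** read-level artifacts (mapping
bias, coverage heterogeneity along the gene), population structure and
relatedness beyond the polygenic background, imputation errors, and any
empirical effect-size spectrum. Passing tests therefore demonstrate the
statistical machinery is correct and calibrated under the stated
generative assumptions — not that real-data preprocessing upstream of
these inputs is handled.

## Problem sizes used in validation

The validation experiments run at the sizes their criteria state: FDR
calibration with 20 cohorts of 1,000 genes (10% eGenes, 1,000
permutations each); beta-approximation fidelity on 100 genes against a
10,000-permutation oracle; aFC recovery at n = 100 for delta ∈
{0.5, 1, 2}; imbalance power on 50 planted and 50 null genes at 500×
coverage; TWAS agreement over 200 genes; colocalization over 50 shared
and 50 distinct replicates in 500-variant LD windows; the non-additive
contrast over 50 cohorts of n = 2,000 with a purely recessive QTL
(hom-alt frequency ≈ 4%, effect calibrated from the noncentrality needed
at the 5e-08 threshold); and the end-to-end cascade over 10 planted and
20 null cohorts (20 genes, 400 variants, 117 + 1,500 samples). In the
cascade experiment the expression normalization is the per-gene inverse
normal transform: cross-sample quantile normalization requires
genome-scale gene panels (a gene's value collapses to its rank among the
genes, which at 20 genes quantizes away real signal), so it is exercised
in the unit tests at realistic panel sizes instead.

## Numerical choices and degenerate inputs

- Inverse normal transform uses the Blom offset (r − 3/8)/(n + 1/4),
  ties averaged; its finite-sample variance (0.944 at n = 50) is the
  analytic value, approached by the tests exactly.
- Quantile normalization maps each sample to the mean sorted profile with
  averaged tie ranks; genes constant in the input are zeroed with a
  warning (after normalization a constant input row is no longer
  constant, so detection happens on the input).
- Intron filters: missingness > 50%, PSI standard deviation < 0.005 (the
  variability cutoff is our choice; only the existence of the filter is
  prescribed), fewer than max(10, 0.1 n) unique values.
- LD pruning: 1000-variant windows (plink syntax without a kb suffix
  denotes variant counts), step 5, r² > 0.2; within a window the member
  of the worst pair with smaller MAF is removed, ties to the later
  position.
- HWE exact test sums probabilities of heterozygote counts no more likely
  than observed, conditional on allele counts; verified against full
  enumeration for ≤30 alleles.
- Beta fit requires values strictly inside (0, 1); permutation minima are
  clipped to [1e-300, 1 − 1e-12].
- Constant coded genotype vectors are skipped (logged as NaN rows);
  conditioning variants are excluded from their own scan.
- Permutations derive from per-phenotype child seeds (SHA-256 of
  seed:phenotype-id), so results are independent of phenotype order and
  reproducible across machines.

## Known limitations

- Permutations shuffle the residualized phenotype; covariate–genotype
  interactions under the null are therefore not preserved (the standard
  scheme in cohort mapping tools).
- The sharing model's fixed covariance dictionary cannot represent
  arbitrary correlation patterns between tissue pairs; with three tissues
  and canonical + one empirical component this is adequate, but lfsr
  calibration under grossly misspecified sharing structures is not
  guaranteed.
- The min-p non-additive statistic is deliberately uncorrected for the
  two codings tested, so its genome-wide type-I error exceeds the
  nominal 5e-08; the emitted lambda_GC quantifies this per run.
- S-PrediXcan with the training cohort as its own LD reference slightly
  overstates |Z| when the GWAS cohort's LD differs; the
  summary-vs-individual agreement criterion bounds this at matched LD
  only.
- The generator's tissues share a single genotype panel and differ only
  through planted masks, hidden factors and sampling noise; cross-tissue
  expression correlation structure beyond that is not modeled.
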