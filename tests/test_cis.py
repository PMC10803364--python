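"""cis mapping: nominal scan, permutations, beta fit, FDR, conditional,
grouped permutations and the trans scan."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from molqtl import cis
from molqtl.io import GenotypeData


def _geno(rng, n, k, maf=0.3, chrom="chr1", spacing=1000):
    hap = rng.binomial(1, maf, size=(2 * n, k)).astype(np.int8)
    dos = hap[0::2] + hap[1::2]
    af = dos.mean(axis=0) / 2
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(1, k + 1) * spacing,
            "id": [f"{chrom}:v{j}" for j in range(k)],
            "ref": "A",
            "alt": "C",
            "maf": np.minimum(af, 1 - af),
        }
    )
    return GenotypeData(variants=variants, haplotypes=hap,
                        samples=[f"s{i}" for i in range(n)])


class TestNominalScan:
    def test_matches_full_design_ols_oracle(self, rng):
        """Residualize-then-regress equals the full design matrix fit."""
        n, k = 10, 4
        G = rng.binomial(2, 0.4, size=(n, k)).astype(float)
        C = rng.standard_normal((n, 2))
        y = 0.8 * G[:, 1] + C @ [0.3, -0.2] + rng.standard_normal(n)
        nom = cis.nominal_scan(y, G, C)
        for j in range(k):
            X = np.column_stack([np.ones(n), G[:, j], C])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            dof = n - X.shape[1]
            s2 = resid @ resid / dof
            cov = s2 * np.linalg.inv(X.T @ X)
            se = np.sqrt(cov[1, 1])
            t = beta[1] / se
            p = 2 * stats.t.sf(abs(t), dof)
            assert nom["slope"][j] == pytest.approx(beta[1], abs=1e-8)
            assert nom["se"][j] == pytest.approx(se, abs=1e-8)
            assert nom["pval"][j] == pytest.approx(p, abs=1e-8)

    def test_self_association_attains_minimum_p(self, rng):
        n, k = 60, 8
        G = rng.binomial(2, 0.4, size=(n, k)).astype(float)
        C = rng.standard_normal((n, 2))
        y = cis.residualize(G[:, 5], C)
        nom = cis.nominal_scan(y, G, C)
        assert nom["pval"].idxmin() == 5
        assert nom["slope"][5] == pytest.approx(1.0, abs=1e-8)

    def test_null_pvalues_uniform(self, rng):
        n = 50
        pvals = []
        for _ in range(500):
            G = rng.binomial(2, 0.3, size=(n, 20)).astype(float)
            y = rng.standard_normal(n)
            pvals.extend(cis.nominal_scan(y, G)["pval"])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_too_few_samples_raises(self, rng):
        with pytest.raises(ValueError):
            cis.nominal_scan(np.ones(4), np.ones((4, 1)), rng.standard_normal((4, 3)))


class TestBetaApprox:
    def test_uniform_draws_give_beta_one_one(self, rng):
        k, n = cis.fit_beta_approx(rng.random(10_000))
        assert k == pytest.approx(1.0, abs=0.1)
        assert n == pytest.approx(1.0, abs=0.1)

    def test_recovers_skewed_beta_parameters(self):
        draws = stats.beta.rvs(0.9, 150, size=10_000, random_state=0)
        k, n = cis.fit_beta_approx(draws)
        assert k == pytest.approx(0.9, rel=0.1)
        assert n == pytest.approx(150, rel=0.1)

    def test_mle_dominates_moment_estimates(self, rng):
        draws = stats.beta.rvs(0.8, 40, size=2000, random_state=1)
        k, n = cis.fit_beta_approx(draws)
        m, v = draws.mean(), draws.var()
        common = m * (1 - m) / v - 1
        k_mom, n_mom = m * common, (1 - m) * common
        assert cis.beta_loglik(draws, k, n) >= cis.beta_loglik(draws, k_mom, n_mom)

    def test_out_of_range_values_rejected(self):
        with pytest.raises(ValueError):
            cis.fit_beta_approx(np.array([0.5, 1.0, 0.2]))


class TestPermutationPass:
    def test_perfect_association_hits_empirical_floor(self, rng):
        n = 80
        G = rng.binomial(2, 0.4, size=(n, 5)).astype(float)
        res = cis.permutation_pass(
            G[:, 2].copy(), G, None, list("abcde"), n_perm=1000,
            rng=np.random.default_rng(0),
        )
        assert res.pval_empirical == pytest.approx(1 / 1001)
        assert res.top_variant == "c"

    def test_seeded_determinism(self, rng):
        n = 50
        G = rng.binomial(2, 0.3, size=(n, 10)).astype(float)
        y = rng.standard_normal(n)
        r1 = cis.permutation_pass(y, G, None, list(range(10)), n_perm=200,
                                  rng=np.random.default_rng(7))
        r2 = cis.permutation_pass(y, G, None, list(range(10)), n_perm=200,
                                  rng=np.random.default_rng(7))
        assert r1 == r2

    def test_adjusted_p_near_uniform_under_null(self, rng):
        adj = []
        for _ in range(300):
            n = 60
            G = rng.binomial(2, 0.3, size=(n, 10)).astype(float)
            y = rng.standard_normal(n)
            res = cis.permutation_pass(
                y, G, None, list(range(10)), n_perm=300,
                rng=np.random.default_rng(rng.integers(2**31 - 1)),
            )
            adj.append(res.pval_beta)
        assert np.mean(adj) == pytest.approx(0.5, abs=0.05)

    def test_empirical_and_beta_p_rank_agree(self, rng):
        emp, adj = [], []
        for i in range(60):
            n = 60
            G = rng.binomial(2, 0.3, size=(n, 10)).astype(float)
            y = 0.05 * i / 10 * G[:, 0] + rng.standard_normal(n)
            res = cis.permutation_pass(
                y, G, None, list(range(10)), n_perm=500,
                rng=np.random.default_rng(i),
            )
            emp.append(res.pval_empirical)
            adj.append(res.pval_beta)
        rho = stats.spearmanr(emp, adj).statistic
        assert rho > 0.97

    def test_too_few_permutations_rejected(self, rng):
        G = rng.binomial(2, 0.3, size=(30, 5)).astype(float)
        with pytest.raises(ValueError):
            cis.permutation_pass(rng.standard_normal(30), G, None,
                                 list(range(5)), n_perm=5)


class TestStoreyFDR:
    def test_all_tiny_pvalues_all_significant(self):
        res = [
            cis.PermutationResult(f"g{i}", "v", 1e-10, 1e-3, 1.0, 10.0, 1e-10, 1000)
            for i in range(20)
        ]
        table = cis.gene_thresholds(res)
        assert table["significant"].all()
        q = table.sort_values("pval_beta")["qvalue"].to_numpy()
        assert np.all(np.diff(q) >= -1e-12)

    def test_uniform_pvalues_match_bh(self, rng):
        p = rng.random(2000)
        q, pi0 = cis.storey_qvalues(p)
        assert pi0 > 0.9
        bh = stats.false_discovery_control(p, method="bh")
        assert np.max(np.abs(q - pi0 * bh)) < 1e-10  # q = pi0 * BH by construction
        assert np.max(np.abs(q - bh)) < 0.12

    def test_thresholds_reproduce_fdr_set(self, rng):
        """Variants called by the per-gene nominal threshold coincide with
        the adjusted-p significance boundary."""
        results = []
        for i in range(200):
            n = 80
            G = rng.binomial(2, 0.4, size=(n, 15)).astype(float)
            delta = 0.8 if i < 40 else 0.0
            y = delta * G[:, 0] + rng.standard_normal(n)
            results.append(
                cis.permutation_pass(
                    y, G, None, list(range(15)), n_perm=300,
                    rng=np.random.default_rng(i), phenotype_id=f"g{i}",
                )
            )
        table = cis.gene_thresholds(results, fdr=0.05)
        p_star = table.attrs["p_star"]
        for _, row in table.iterrows():
            if row["significant"]:
                # nominal p at the threshold maps back to the boundary
                implied = stats.beta.cdf(
                    row["pval_nominal_threshold"], row["beta_k"], row["beta_n"]
                )
                assert implied == pytest.approx(p_star, rel=1e-6)
                assert row["pval_beta"] <= p_star
            else:
                assert np.isnan(row["pval_nominal_threshold"])
                assert row["pval_beta"] >= p_star


class TestConditionalPass:
    def _window(self, rng, n=150, k=30):
        G = rng.binomial(2, 0.35, size=(n, k)).astype(float)
        ids = [f"v{j}" for j in range(k)]
        pos = np.arange(k) * 10_000
        return G, ids, pos

    def test_single_causal_yields_single_signal(self, rng):
        hits = 0
        for trial in range(30):
            G, ids, pos = self._window(rng)
            y = 0.7 * G[:, 12] + rng.standard_normal(len(G))
            sigs = cis.conditional_pass(y, G, None, ids, pos, threshold=1e-3)
            if len(sigs) == 1:
                j = ids.index(sigs[0].top_variant)
                r2 = np.corrcoef(G[:, j], G[:, 12])[0, 1] ** 2
                hits += (j == 12) or (r2 > 0.8)
        assert hits >= 27  # >= 90% of trials

    def test_two_unlinked_causals_yield_two_signals(self, rng):
        found = 0
        for _ in range(20):
            G, ids, pos = self._window(rng, n=300)
            y = 0.8 * G[:, 3] + 0.8 * G[:, 20] + rng.standard_normal(len(G))
            sigs = cis.conditional_pass(y, G, None, ids, pos, threshold=1e-3)
            found += len(sigs) == 2
        assert found >= 16

    def test_null_phenotype_yields_no_signal(self, rng):
        G, ids, pos = self._window(rng)
        y = rng.standard_normal(len(G))
        assert cis.conditional_pass(y, G, None, ids, pos, threshold=1e-4) == []

    def test_missing_threshold_raises(self, rng):
        G, ids, pos = self._window(rng)
        with pytest.raises(ValueError):
            cis.conditional_pass(rng.standard_normal(len(G)), G, None, ids,
                                 pos, threshold=np.nan)


class TestGroupedPermutations:
    def test_group_of_one_reduces_to_single_pass(self, rng):
        n = 60
        G = rng.binomial(2, 0.3, size=(n, 8)).astype(float)
        y = 0.4 * G[:, 1] + rng.standard_normal(n)
        single = cis.permutation_pass(
            y, G, None, list(range(8)), n_perm=300, rng=np.random.default_rng(3)
        )
        grouped = cis.grouped_permutation_pass(
            y[None, :], G, None, list(range(8)), n_perm=300,
            rng=np.random.default_rng(3),
        )
        assert grouped.pval_nominal == pytest.approx(single.pval_nominal)
        assert grouped.top_variant == single.top_variant
        # same seed, same permutation statistics
        assert grouped.pval_empirical == pytest.approx(single.pval_empirical, abs=0.02)

    def test_identical_groups_and_seeds_identical_results(self, rng):
        n = 50
        G = rng.binomial(2, 0.3, size=(n, 6)).astype(float)
        Y = rng.standard_normal((3, n))
        r1 = cis.grouped_permutation_pass(Y, G, None, list(range(6)), n_perm=200,
                                          rng=np.random.default_rng(5))
        r2 = cis.grouped_permutation_pass(Y, G, None, list(range(6)), n_perm=200,
                                          rng=np.random.default_rng(5))
        assert r1 == r2

    def test_noise_junction_does_not_inflate_significance(self, rng):
        """Adding a pure-noise junction leaves the group-adjusted p no more
        significant on average (the group minimum is re-calibrated)."""
        diffs = []
        for i in range(60):
            n = 60
            G = rng.binomial(2, 0.3, size=(n, 6)).astype(float)
            y1 = 0.35 * G[:, 0] + rng.standard_normal(n)
            noise = rng.standard_normal(n)
            a = cis.grouped_permutation_pass(
                y1[None, :], G, None, list(range(6)), n_perm=300,
                rng=np.random.default_rng(i),
            )
            b = cis.grouped_permutation_pass(
                np.vstack([y1, noise]), G, None, list(range(6)), n_perm=300,
                rng=np.random.default_rng(i),
            )
            diffs.append(b.pval_beta - a.pval_beta)
        assert np.mean(diffs) > -0.02


class TestTransScan:
    def test_cis_window_excluded(self, rng):
        geno = _geno(rng, 60, 30, spacing=400_000)  # 12 Mb span
        phen = pd.DataFrame(
            rng.standard_normal((2, 60)), index=["p1", "p2"],
            columns=geno.samples,
        )
        anchors = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "pos": [400_000, 6_000_000]},
            index=["p1", "p2"],
        )
        out = cis.trans_scan(phen, anchors, geno, n_perm=20)
        tested = out[out["phenotype"] == "p1"]["variant"]
        pos = geno.variants.set_index("id")["pos"]
        assert (np.abs(pos.loc[tested] - 400_000) > 5_000_000).all()

    def test_planted_trans_effect_detected(self, rng):
        found = 0
        for i in range(15):
            local = np.random.default_rng(i)
            geno = _geno(local, 150, 40, spacing=400_000)
            dos = geno.dosages
            y = 0.9 * dos[:, 35] + local.standard_normal(150)
            phen = pd.DataFrame(y[None, :], index=["p"], columns=geno.samples)
            anchors = pd.DataFrame({"chrom": ["chr1"], "pos": [400_000]}, index=["p"])
            out = cis.trans_scan(phen, anchors, geno, n_perm=50, seed=i)
            hit = out[(out["variant"] == geno.variants["id"][35]) & out["significant"]]
            found += len(hit) > 0
        assert found >= 13  # >= ~90%

    def test_null_data_rarely_significant(self, rng):
        # the permutation-rank FDR has an irreducible ~1/(n_perm+1)
        # per-dataset false-call floor; at 100 permutations the clean rate
        # must still be >= 95% of seeds
        clean = 0
        n_seeds = 40
        for i in range(n_seeds):
            local = np.random.default_rng(100 + i)
            geno = _geno(local, 80, 30, spacing=400_000)
            phen = pd.DataFrame(
                local.standard_normal((3, 80)), index=list("abc"),
                columns=geno.samples,
            )
            anchors = pd.DataFrame(
                {"chrom": ["chr1"] * 3, "pos": [0, 0, 0]}, index=list("abc")
            )
            out = cis.trans_scan(phen, anchors, geno, n_perm=100, seed=i)
            clean += not out["significant"].any()
        assert clean >= 0.95 * n_seeds

    def test_ld_filter_drops_linked_hits(self, rng):
        # n large enough that null r2 noise stays below the 0.01 cut
        geno = _geno(rng, 3000, 10)
        hap = geno.haplotypes.copy()
        hap[:, 1] = hap[:, 0]  # perfect LD pair
        geno = GenotypeData(geno.variants, hap, geno.samples)
        hits = pd.DataFrame(
            {"phenotype": ["g", "g", "h"], "variant":
             [geno.variants["id"][1], geno.variants["id"][5], geno.variants["id"][1]]}
        )
        cis_vars = {"g": [geno.variants["id"][0]]}
        out = cis.trans_ld_filter(hits, cis_vars, geno, r2_cut=0.01)
        # linked hit for gene g removed; unlinked kept; gene h (no cis
        # signals) untouched
        assert len(out) == 2
        assert not (
            (out["phenotype"] == "g") & (out["variant"] == geno.variants["id"][1])
        ).any()


class TestMapperEndToEnd:
    def test_planted_eqtl_found_and_nulls_controlled(self):
        from molqtl import phenotypes as ph
        from molqtl.sim import SimConfig, simulate_cohort

        # dedicated cohort with enough samples and strong planted effects
        # for the permutation pass to have power
        cohort = simulate_cohort(
            SimConfig(
                seed=21,
                n_variants=300,
                n_genes=25,
                n_clusters=8,
                n_samples_per_tissue=(100, 10, 10),
                n_gwas_samples=100,
                chromosome_length=8_000_000,
                prop_egenes=0.5,
                afc_magnitude_range=(1.0, 2.0),
            )
        )
        tissue = "testis"
        counts = cohort.expression_counts[tissue]
        lengths = pd.Series(
            cohort.gene_models["length"].to_numpy(),
            index=cohort.gene_models["gene"],
        )
        tpm = ph.compute_tpm(counts, lengths)
        keep = ph.filter_expressed_genes(counts, tpm)
        norm = ph.normalize_expression(tpm.loc[keep])
        anchors = pd.DataFrame(
            {
                "chrom": cohort.gene_models["chrom"].to_numpy(),
                "pos": cohort.gene_models["tss"].to_numpy(),
            },
            index=cohort.gene_models["gene"],
        ).loc[keep]
        geno = cohort.genotypes.subset_samples(
            [cohort.genotypes.samples.index(s) for s in counts.columns]
        )
        mapper = cis.CisQTLMapper(norm, anchors, geno)
        res = mapper.fit(n_permutations=300, seed=0)
        strong = cohort.truth.eqtl_for_tissue(tissue)
        strong = set(strong[strong["rank"] == 1]["gene"]) & set(norm.index)
        found = set(res.significant["phenotype_id"])
        assert len(strong) >= 3
        assert len(strong & found) / len(strong) >= 0.6
        null_genes = set(norm.index) - set(cohort.truth.eqtl["gene"])
        assert len(found & null_genes) <= max(1, 0.2 * len(null_genes))
        assert "cis-QTL permutation pass" in res.summary()
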