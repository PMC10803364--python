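"""Molecular phenotypes: TPM, filters, normalization, clustering, PSI."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from molqtl import phenotypes as ph


class TestTPM:
    def test_length_normalization_ratio(self):
        counts = pd.DataFrame({"s1": [100, 100]}, index=["a", "b"])
        lengths = pd.Series([1000, 2000], index=["a", "b"])
        tpm = ph.compute_tpm(counts, lengths)
        assert tpm.loc["a", "s1"] / tpm.loc["b", "s1"] == pytest.approx(2.0)

    def test_single_gene_is_million(self):
        tpm = ph.compute_tpm(
            pd.DataFrame({"s": [7]}, index=["g"]), pd.Series([500], index=["g"])
        )
        assert tpm.iloc[0, 0] == pytest.approx(1e6)

    def test_matches_hand_computation(self):
        counts = pd.DataFrame(
            {"s1": [10, 20, 5, 0], "s2": [3, 9, 1, 2]},
            index=list("abcd"),
        )
        lengths = pd.Series([100, 400, 50, 200], index=list("abcd"))
        tpm = ph.compute_tpm(counts, lengths)
        rate = counts.div(lengths, axis=0)
        expect = rate / rate.sum(axis=0) * 1e6
        pd.testing.assert_frame_equal(tpm, expect)
        np.testing.assert_allclose(tpm.sum(axis=0), 1e6, atol=1e-3)

    def test_zero_sample_raises(self):
        with pytest.raises(ValueError):
            ph.compute_tpm(
                pd.DataFrame({"s": [0, 0]}, index=["a", "b"]),
                pd.Series([100, 100], index=["a", "b"]),
            )


class TestExpressionFilter:
    def test_inclusive_boundary_semantics(self):
        # exactly 0.1 TPM and 6 reads in exactly 20% of samples -> kept
        n = 10
        counts = pd.DataFrame(
            [[6, 6] + [0] * 8, [5] * 10], index=["kept", "dropped"],
            columns=[f"s{i}" for i in range(n)],
        )
        tpm = pd.DataFrame(
            [[0.1, 0.1] + [0.0] * 8, [0.05] * 10], index=["kept", "dropped"],
            columns=counts.columns,
        )
        kept = ph.filter_expressed_genes(counts, tpm)
        assert list(kept) == ["kept"]

    def test_both_conditions_required_jointly(self):
        counts = pd.DataFrame([[100, 0, 0, 0]], index=["g"],
                              columns=list("abcd"))
        tpm = pd.DataFrame([[0.05, 5.0, 5.0, 5.0]], index=["g"],
                           columns=list("abcd"))
        # no sample passes both thresholds at once
        assert len(ph.filter_expressed_genes(counts, tpm)) == 0


class TestNormalization:
    @staticmethod
    def _tie_free_tpm(n=50):
        # columns are cyclic shifts of one sorted profile: quantile
        # normalization is then exact and every row is tie-free
        v = np.sort(np.random.default_rng(1).lognormal(2, 1, n))
        arr = np.empty((n, n))
        for j in range(n):
            arr[:, j] = np.roll(v, j)
        return pd.DataFrame(arr, columns=[f"s{j}" for j in range(n)])

    def test_output_rows_exact_standard_normal_shape_when_tie_free(self):
        n = 50
        tpm = self._tie_free_tpm(n)
        norm = ph.normalize_expression(tpm)
        assert np.abs(norm.mean(axis=1)).max() < 1e-8
        v = norm.var(axis=1, ddof=0)
        # every tie-free row carries exactly the Blom INT quantiles, whose
        # finite-sample variance is the analytic value (-> 1 as n grows)
        from scipy.stats import norm as normal

        quantiles = normal.ppf((np.arange(1, n + 1) - 3 / 8) / (n + 1 / 4))
        expected_var = quantiles.var()
        np.testing.assert_allclose(v, expected_var, rtol=1e-9)
        assert expected_var > 0.9

    def test_output_rows_near_standard_normal_on_noisy_data(self, rng):
        tpm = pd.DataFrame(
            rng.lognormal(2, 1, size=(30, 80)),
            columns=[f"s{i}" for i in range(80)],
        )
        norm = ph.normalize_expression(tpm)
        assert np.abs(norm.mean(axis=1)).max() < 0.05
        assert np.allclose(norm.var(axis=1, ddof=0), 1.0, rtol=0.1)

    def test_rank_preservation_for_tie_free_rows(self):
        tpm = self._tie_free_tpm()
        norm = ph.normalize_expression(tpm)
        for i in range(len(tpm)):
            rho, _ = spearmanr(tpm.iloc[i], norm.iloc[i])
            assert rho == pytest.approx(1.0)

    def test_quantile_normalization_equalizes_rank_identical_columns(self, rng):
        base = np.sort(rng.lognormal(1, 1, 20))
        df = pd.DataFrame({"a": base, "b": base * 3 + 1})
        qn = ph.quantile_normalize_columns(df)
        np.testing.assert_allclose(qn["a"], qn["b"])

    def test_constant_gene_becomes_zeros_with_warning(self):
        tpm = pd.DataFrame(
            np.vstack([np.ones(20), np.random.default_rng(0).lognormal(1, 1, 20)])
        )
        with pytest.warns(UserWarning):
            norm = ph.normalize_expression(tpm)
        assert (norm.iloc[0] == 0).all()


class TestIntronClustering:
    def _junc(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])

    def test_shared_donor_forms_cluster(self):
        jx = self._junc([("chr1", 100, 500, "+"), ("chr1", 100, 800, "+")])
        out = ph.cluster_introns(jx)
        assert out["cluster"].nunique() == 1
        assert len(out) == 2

    def test_singletons_dropped(self):
        jx = self._junc([("chr1", 100, 500, "+"), ("chr1", 1000, 2000, "+")])
        assert len(ph.cluster_introns(jx)) == 0

    def test_strand_separation(self):
        jx = self._junc([("chr1", 100, 500, "+"), ("chr1", 100, 800, "-")])
        assert len(ph.cluster_introns(jx)) == 0

    def test_matches_union_find_oracle(self):
        rng = np.random.default_rng(3)
        sites = rng.choice(np.arange(100, 2000, 50), size=24, replace=False)
        rows = []
        for _ in range(12):
            a, b = rng.choice(sites, 2, replace=False)
            rows.append(("chr1", min(a, b), max(a, b), "+"))
        jx = self._junc(rows)
        out = ph.cluster_introns(jx)

        # independent union-find over shared start/end coordinates
        parent = list(range(len(jx)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(jx)):
            for j in range(i + 1, len(jx)):
                if (
                    jx.loc[i, "start"] == jx.loc[j, "start"]
                    or jx.loc[i, "end"] == jx.loc[j, "end"]
                ):
                    parent[find(i)] = find(j)
        from collections import defaultdict

        comps = defaultdict(set)
        for i in range(len(jx)):
            comps[find(i)].add((jx.loc[i, "start"], jx.loc[i, "end"]))
        oracle = {frozenset(c) for c in comps.values() if len(c) >= 2}
        got = {
            frozenset(zip(grp["start"], grp["end"]))
            for _, grp in out.groupby("cluster")
        }
        assert got == oracle

    def test_malformed_interval_raises(self):
        with pytest.raises(ValueError):
            ph.cluster_introns(self._junc([("chr1", 500, 100, "+")]))


class TestPSI:
    def test_simple_fractions_and_sum(self):
        counts = pd.DataFrame({"s1": [30, 10], "s2": [0, 0]}, index=["j1", "j2"])
        clusters = pd.Series(["c", "c"], index=["j1", "j2"])
        psi = ph.compute_psi(counts, clusters)
        assert psi.loc["j1", "s1"] == pytest.approx(0.75)
        assert psi.loc["j2", "s1"] == pytest.approx(0.25)
        assert psi["s2"].isna().all()
        assert psi["s1"].sum() == pytest.approx(1.0)

    def test_cluster_of_one_rejected(self):
        with pytest.raises(ValueError):
            ph.compute_psi(
                pd.DataFrame({"s": [3]}, index=["j"]), pd.Series(["c"], index=["j"])
            )


class TestIntronFilters:
    def test_missingness_variability_unique_filters(self, rng):
        n = 117
        cols = [f"s{i}" for i in range(n)]
        good = rng.uniform(0.2, 0.8, n)
        missing = np.where(rng.random(n) < 0.65, np.nan, 0.5 + 0.3 * rng.random(n))
        constant = np.full(n, 0.4)
        few_unique = np.tile(np.linspace(0.1, 0.9, 11), 20)[:n]  # 11 unique < 11.7
        psi = pd.DataFrame(
            [good, missing, constant, few_unique],
            index=["good", "missing", "constant", "few_unique"],
            columns=cols,
        )
        out = ph.filter_and_normalize_introns(psi)
        assert list(out.index) == ["good"]
        # normalized row: zero mean, near-unit variance
        assert abs(out.loc["good"].mean()) < 1e-8

    def test_filters_never_change_values_normalization_keeps_count(self, rng):
        psi = pd.DataFrame(rng.uniform(0, 1, size=(6, 60)))
        out = ph.filter_and_normalize_introns(psi)
        assert len(out) == 6  # nothing dropped for clean data
        assert out.shape[1] == 60


class TestHiddenFactors:
    def test_recovers_planted_factor_space(self, rng):
        n, g, k = 80, 300, 3
        F = rng.standard_normal((n, k))
        L = rng.standard_normal((k, g))
        X = (F @ L + 0.5 * rng.standard_normal((n, g))).T
        mat = pd.DataFrame(X, columns=[f"s{i}" for i in range(n)])
        est = ph.estimate_hidden_factors(mat, k=3)
        # canonical correlation between estimated and true factor spaces
        Q1, _ = np.linalg.qr(est.T.to_numpy())
        Q2, _ = np.linalg.qr(F - F.mean(0))
        sv = np.linalg.svd(Q1.T @ Q2, compute_uv=False)
        assert sv.min() > 0.9

    def test_orthogonal_scores(self, rng):
        mat = pd.DataFrame(rng.standard_normal((50, 40)))
        est = ph.estimate_hidden_factors(mat, k=5).T.to_numpy()
        off = est.T @ est - np.eye(5)
        assert np.abs(off).max() < 1e-8

    def test_k_zero_and_k_too_large(self, rng):
        mat = pd.DataFrame(rng.standard_normal((20, 30)))
        assert ph.estimate_hidden_factors(mat, k=0).empty
        with pytest.raises(ValueError):
            ph.estimate_hidden_factors(mat, k=30)


class TestTissueComparisons:
    def test_enrichment_classes(self):
        mean_tpm = pd.DataFrame(
            {
                "testis": [100.0, 100.0, 50.0, 3.0],
                "epididymis": [1.0, 3.0, 40.0, 0.0],
                "vas_deferens": [1.0, 1.0, 30.0, 0.0],
            },
            index=["enriched", "shared", "flat", "specific"],
        )
        expressed = {
            "testis": {"enriched", "shared", "flat", "specific"},
            "epididymis": {"enriched", "shared", "flat"},
            "vas_deferens": {"enriched", "shared", "flat"},
        }
        cls = ph.classify_tissue_enrichment(mean_tpm, expressed)
        assert cls["enriched"] == "highly_enriched"  # 100 >= 50*1 and 50*1
        assert cls["shared"] == "shared"             # 100/3 < 50
        assert cls["flat"] == "shared"
        assert cls["specific"] == "specific"

    def test_similarity_self_is_one_and_null_is_small(self, rng):
        a = pd.DataFrame(rng.lognormal(1, 1, size=(1000, 10)))
        b = pd.DataFrame(rng.lognormal(1, 1, size=(1000, 10)))
        assert ph.tissue_similarity(a, a) == pytest.approx(1.0)
        assert abs(ph.tissue_similarity(a, b)) < 0.1

    def test_similarity_orders_by_planted_sharing(self, rng):
        base = rng.lognormal(2, 1, 800)
        high = pd.DataFrame({"m": np.where(rng.random(800) < 0.9, base,
                                           rng.lognormal(2, 1, 800))})
        low = pd.DataFrame({"m": np.where(rng.random(800) < 0.1, base,
                                          rng.lognormal(2, 1, 800))})
        ref = pd.DataFrame({"m": base})
        assert ph.tissue_similarity(ref, high) > ph.tissue_similarity(ref, low)
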