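"""Mixed-model GWAS: REML, MLMA scan, M1/M2 codings, peaks, conditioning."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from molqtl.genotype import compute_grm
from molqtl.gwas import (
    GENOME_WIDE_ALPHA,
    MixedModelGWAS,
    detect_peaks,
    genomic_inflation,
    mlma_scan,
    recode_nonadditive,
    reml_loglik,
    reml_null_model,
)


def _panel(rng, n, m, maf_low=0.1, maf_high=0.5):
    X = rng.binomial(2, rng.uniform(maf_low, maf_high, m), size=(n, m)).astype(float)
    variants = pd.DataFrame(
        {"id": [f"v{j}" for j in range(m)], "chrom": "chr1",
         "pos": np.arange(m) * 10_000 + 1}
    )
    return X, variants


class TestREML:
    def test_null_heritability_recovered(self, rng):
        # REML sampling sd of h2 under the null is ~ sqrt(2m)/n, so the
        # cohort must be large relative to the marker count
        hits = 0
        for s in range(15):
            local = np.random.default_rng(s)
            X, _ = _panel(local, 1000, 400)
            grm = compute_grm(X)
            y = local.standard_normal(1000)
            vc, _ = reml_null_model(y, grm)
            hits += vc.lam < 0.05 or vc.h2 < 0.05
        assert hits >= 0.9 * 15

    def test_simulated_h2_recovered(self, rng):
        hits = 0
        for s in range(10):
            local = np.random.default_rng(100 + s)
            X, _ = _panel(local, 800, 600)
            Z = (X - X.mean(0)) / X.std(0)
            u = Z @ local.normal(0, np.sqrt(0.5 / 600), 600)
            y = u + local.normal(0, np.sqrt(0.5), 800)
            vc, _ = reml_null_model(y, compute_grm(X))
            hits += 0.35 <= vc.h2 <= 0.65
        assert hits >= 8

    def test_optimum_beats_grid_oracle(self, rng):
        X, _ = _panel(rng, 200, 300)
        grm = compute_grm(X)
        Z = (X - X.mean(0)) / X.std(0)
        y = Z @ rng.normal(0, 0.03, 300) + rng.standard_normal(200)
        vc, rot = reml_null_model(y, grm)
        best = reml_loglik(np.log(max(rot["lam"], 1e-5)), rot["yt"], rot["Xt"], rot["d"])
        grid = np.linspace(np.log(1e-5), np.log(1e5), 100)
        grid_best = max(reml_loglik(t, rot["yt"], rot["Xt"], rot["d"]) for t in grid)
        assert best >= grid_best - 1e-4

    def test_non_psd_grm_rejected(self, rng):
        from molqtl.genotype import GRM

        bad = GRM(matrix=np.array([[1.0, 2.0], [2.0, 1.0]]), n_variants_used=1)
        with pytest.raises(ValueError):
            reml_null_model(np.zeros(30), GRM(
                matrix=np.diag(np.r_[np.ones(29), -1.0]), n_variants_used=10
            ))


class TestMLMA:
    def test_identity_grm_reduces_to_ols(self, rng):
        from molqtl.genotype import GRM

        n, m = 100, 20
        X, variants = _panel(rng, n, m)
        y = 0.4 * X[:, 3] + rng.standard_normal(n)
        grm = GRM(matrix=np.eye(n), n_variants_used=1)
        model = MixedModelGWAS(y, X, variants, grm)
        res = model.fit(model="additive")
        for j in range(m):
            D = np.column_stack([np.ones(n), X[:, j]])
            beta, *_ = np.linalg.lstsq(D, y, rcond=None)
            r = y - D @ beta
            s2 = r @ r / (n - 2)
            se = np.sqrt(s2 * np.linalg.inv(D.T @ D)[1, 1])
            p = 2 * stats.t.sf(abs(beta[1] / se), n - 2)
            assert res.table["beta"][j] == pytest.approx(beta[1], abs=1e-6)
            assert res.table["pval"][j] == pytest.approx(p, rel=1e-4, abs=1e-10)

    def test_matches_direct_gls_oracle(self, rng):
        """Effect and se equal the explicit GLS solution built from the full
        covariance inverse on a small panel with an arbitrary PSD GRM."""
        n, m = 40, 8
        X, variants = _panel(rng, n, m)
        A = rng.standard_normal((n, n))
        K = A @ A.T / n
        K = K / np.diag(K).mean()
        from molqtl.genotype import GRM

        grm = GRM(matrix=(K + K.T) / 2, n_variants_used=n)
        y = rng.standard_normal(n)
        vc, rot = reml_null_model(y, grm)
        tab = mlma_scan(X, rot)
        lam = rot["lam"]
        V = lam * grm.matrix + np.eye(n)
        Vi = np.linalg.inv(V)
        for j in range(m):
            D = np.column_stack([np.ones(n), X[:, j]])
            DVD = D.T @ Vi @ D
            beta = np.linalg.solve(DVD, D.T @ Vi @ y)
            r = y - D @ beta
            s2 = (r @ Vi @ r) / (n - 2)
            se = np.sqrt(s2 * np.linalg.inv(DVD)[1, 1])
            assert tab["beta"][j] == pytest.approx(beta[1], abs=1e-6)
            assert tab["se"][j] == pytest.approx(se, abs=1e-6)

    def test_constant_coded_vector_skipped(self, rng):
        n = 60
        X, variants = _panel(rng, n, 3)
        X[:, 0] = 1.0
        grm = compute_grm(X[:, 1:])
        model = MixedModelGWAS(rng.standard_normal(n), X, variants, grm)
        res = model.fit(model="additive")
        assert np.isnan(res.table["pval"][0])
        assert res.table["pval"][1:].notna().all()


class TestRecode:
    def test_coding_definitions(self):
        m1, m2, ok1, ok2 = recode_nonadditive(np.array([0.0, 1.0, 2.0, 2.0]))
        np.testing.assert_array_equal(m1, [1, 0, 0, 0])
        np.testing.assert_array_equal(m2, [0, 0, 1, 1])

    def test_rare_coding_ineligible(self, rng):
        # hom-alt frequency 0.3% -> M2 ineligible
        g = np.zeros(1000)
        g[:500] = 1.0
        g[:3] = 2.0
        _, m2, ok1, ok2 = recode_nonadditive(g)
        assert not ok2
        assert ok1

    def test_all_het_variant_fully_ineligible(self):
        g = np.ones(100)
        m1, m2, ok1, ok2 = recode_nonadditive(g)
        assert not ok1 and not ok2
        assert m1.sum() == 0 and m2.sum() == 0


class TestNonAdditiveScan:
    def test_min_p_and_winning_coding(self, rng):
        n = 500
        X, variants = _panel(rng, n, 10, maf_low=0.2, maf_high=0.4)
        hom = (X[:, 4] == 2).astype(float)
        y = 1.0 * hom + rng.standard_normal(n)
        grm = compute_grm(X)
        res = MixedModelGWAS(y, X, variants, grm).fit(model="nonadditive")
        row = res.table.iloc[4]
        assert row["pval"] == min(row["pval_m1"], row["pval_m2"])
        assert row["coding"] == "M2"
        assert (res.table["pval"] <= res.table[["pval_m1", "pval_m2"]].min(axis=1)
                + 1e-15).all()

    def test_min_p_inflation_reported(self, rng):
        n = 800
        X, variants = _panel(rng, n, 300, maf_low=0.15, maf_high=0.45)
        y = rng.standard_normal(n)
        grm = compute_grm(X)
        res = MixedModelGWAS(y, X, variants, grm).fit(model="nonadditive")
        lam = res.lambda_gc
        # min-p over two codings is stochastically smaller than uniform;
        # its inflation is reported and sits near the analytic ~2.3
        assert 1.2 < lam < 3.5
        assert f"{lam:.3f}" in res.summary()

    def test_recessive_contrast(self):
        from molqtl.validation import nonadditive_power

        out = nonadditive_power(5, n_seeds=5)
        assert out["recessive_only_rate"] >= 0.6


class TestConditional:
    def test_conditioning_on_causal_absorbs_peak(self, rng):
        hits = 0
        for s in range(10):
            local = np.random.default_rng(s)
            n = 800
            X, variants = _panel(local, n, 60, maf_low=0.2, maf_high=0.4)
            y = 0.35 * X[:, 30] + local.standard_normal(n)
            grm = compute_grm(X)
            model = MixedModelGWAS(y, X, variants, grm)
            base = model.fit(model="additive")
            if np.nanmin(base.table["pval"]) >= GENOME_WIDE_ALPHA:
                hits += 1  # nothing to absorb
                continue
            cond = model.fit(model="additive", condition_on=["v30"])
            hits += np.nanmin(cond.table["pval"].to_numpy()) >= GENOME_WIDE_ALPHA
        assert hits >= 9

    def test_conditioning_on_null_variant_keeps_peak(self, rng):
        n = 800
        X, variants = _panel(rng, n, 40, maf_low=0.2, maf_high=0.4)
        y = 0.5 * X[:, 10] + rng.standard_normal(n)
        grm = compute_grm(X)
        model = MixedModelGWAS(y, X, variants, grm)
        base = model.fit(model="additive")
        cond = model.fit(model="additive", condition_on=["v39"])
        p0 = base.table["pval"][10]
        p1 = cond.table["pval"][10]
        assert abs(np.log10(p1) - np.log10(p0)) < 1.0

    def test_tested_variant_equal_to_conditioning_skipped(self, rng):
        n = 200
        X, variants = _panel(rng, n, 5)
        grm = compute_grm(X)
        model = MixedModelGWAS(rng.standard_normal(n), X, variants, grm)
        res = model.fit(model="additive", condition_on=["v2"])
        assert np.isnan(res.table["pval"][2])


class TestPeaks:
    def test_no_significant_no_peaks(self):
        df = pd.DataFrame(
            {"variant": ["a"], "chrom": ["chr1"], "pos": [100], "pval": [0.5]}
        )
        assert detect_peaks(df) == []

    def test_nearby_hits_merge(self):
        df = pd.DataFrame(
            {
                "variant": ["a", "b"],
                "chrom": ["chr1", "chr1"],
                "pos": [1_000_000, 1_500_000],
                "pval": [1e-9, 1e-10],
            }
        )
        peaks = detect_peaks(df)
        assert len(peaks) == 1
        assert peaks[0].lead_variant == "b"
        assert set(peaks[0].members) == {"a", "b"}

    def test_matches_interval_merging_oracle(self, rng):
        m = 1000
        df = pd.DataFrame(
            {
                "variant": [f"v{j}" for j in range(m)],
                "chrom": rng.choice(["chr1", "chr2"], m),
                "pos": rng.integers(1, 50_000_000, m),
                "pval": 10.0 ** rng.uniform(-12, 0, m),
            }
        )
        peaks = detect_peaks(df)
        # oracle: simple interval merging per chromosome
        expected = 0
        for chrom, grp in df[df["pval"] < GENOME_WIDE_ALPHA].groupby("chrom"):
            pos = np.sort(grp["pos"].to_numpy())
            expected += 1 + int(np.sum(np.diff(pos) > 1_000_000))
        assert len(peaks) == expected
        for p in peaks:
            assert p.lead_pval < GENOME_WIDE_ALPHA

    def test_additive_null_rarely_peaks(self, rng):
        clean = 0
        for s in range(10):
            local = np.random.default_rng(1000 + s)
            X, variants = _panel(local, 500, 300)
            y = local.standard_normal(500)
            res = MixedModelGWAS(y, X, variants, compute_grm(X)).fit()
            clean += len(res.peaks()) == 0
        assert clean >= 9
        assert genomic_inflation(res.table["pval"].to_numpy()) < 1.3
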