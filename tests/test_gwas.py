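"""Per-platform GWAS, IVW meta-analysis, lambda_GC, clumping and PRS."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ckm_topics.gwas import (GwasError, build_prs, clump_leads, gwas_platform,
                             lambda_gc, meta_analyze, meta_fixed, qq_table,
                             score_prs, validate_prs)


class TestGwasPlatform:
    def test_matches_statsmodels_full_ols(self, rng):
        import statsmodels.api as sm

        n = 200
        g = rng.integers(0, 3, size=n).astype(float)
        cov = rng.normal(size=(n, 2))
        y = 0.1 * g + cov @ [0.5, -0.2] + rng.normal(size=n)
        tab = gwas_platform(y, g, cov)
        X = sm.add_constant(np.column_stack([cov, g]))
        fit = sm.OLS(y, X).fit()
        assert tab.loc[0, "beta"] == pytest.approx(fit.params[-1], abs=1e-10)
        assert tab.loc[0, "se"] == pytest.approx(fit.bse[-1], abs=1e-10)
        assert tab.loc[0, "p"] == pytest.approx(fit.pvalues[-1], abs=1e-10)

    def test_null_pvalues_are_uniform(self, rng):
        n, m = 500, 1500
        G = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        y = rng.normal(size=n)
        tab = gwas_platform(y, G)
        ok = ~tab["excluded"]
        ks = stats.kstest(tab.loc[ok, "p"], "uniform")
        assert ks.pvalue > 0.01

    def test_monomorphic_variant_flagged_and_nan(self, rng):
        n = 100
        G = np.column_stack([np.ones(n), rng.binomial(2, 0.4, size=n)])
        tab = gwas_platform(rng.normal(size=n), G)
        assert bool(tab.loc[0, "excluded"])
        assert np.isnan(tab.loc[0, "beta"])
        assert not tab.loc[1, "excluded"]


class TestMetaFixed:
    def test_hand_computed_ivw(self):
        b, se, p = meta_fixed([0.2, 0.4], [0.1, 0.1])
        assert b == pytest.approx(0.3, abs=1e-12)
        assert se == pytest.approx(0.1 / np.sqrt(2), abs=1e-12)
        z = b / se
        assert p == pytest.approx(2 * stats.norm.sf(z), abs=1e-15)

    def test_single_platform_is_identity(self):
        b, se, p = meta_fixed([0.25], [0.08])
        assert (b, se) == (0.25, 0.08)

    def test_infinite_se_platform_contributes_nothing(self):
        b1, se1, _ = meta_fixed([0.2, 5.0], [0.1, 1e12])
        assert b1 == pytest.approx(0.2, abs=1e-9)
        assert se1 == pytest.approx(0.1, abs=1e-9)

    def test_platform_order_invariance(self, rng):
        b = rng.normal(size=3)
        s = rng.uniform(0.05, 0.2, size=3)
        r1 = meta_fixed(b, s)
        r2 = meta_fixed(b[::-1], s[::-1])
        np.testing.assert_allclose(r1, r2, atol=1e-12)

    def test_all_undefined_gives_nan(self):
        b, se, p = meta_fixed([np.nan], [np.nan])
        assert np.isnan(b) and np.isnan(se) and np.isnan(p)

    def test_matches_stacked_wls_oracle(self, rng):
        # shared-variance simulation: IVW meta equals OLS on stacked data
        # with platform-specific intercepts
        n = 400
        betas, ses = [], []
        ys, gs, plats = [], [], []
        for p_i in range(3):
            g = rng.binomial(2, 0.3, size=n).astype(float)
            y = 0.15 * g + rng.normal(size=n)
            tab = gwas_platform(y, g)
            betas.append(tab.loc[0, "beta"])
            ses.append(tab.loc[0, "se"])
            ys.append(y), gs.append(g), plats.append(np.full(n, p_i))
        mb, _, _ = meta_fixed(betas, ses)
        import statsmodels.api as sm

        plat = np.concatenate(plats)
        X = np.column_stack([pd.get_dummies(plat, dtype=float).to_numpy(),
                             np.concatenate(gs)])
        fit = sm.OLS(np.concatenate(ys), X).fit()
        assert mb == pytest.approx(fit.params[-1], rel=0.02)


class TestLambdaGC:
    def test_constant_half_pvalues_give_unity(self):
        with pytest.warns(UserWarning):
            lam = lambda_gc(np.full(50, 0.5))
        assert lam == pytest.approx(1.0, abs=1e-4)

    def test_inflation_increases_lambda(self, rng):
        p = rng.uniform(size=5000)
        assert lambda_gc(p / 2) > lambda_gc(p)

    def test_null_lambda_near_one(self, rng):
        p = rng.uniform(size=20_000)
        assert 0.95 < lambda_gc(p) < 1.05


class TestClumping:
    def _table(self, chrom, pos, p):
        return pd.DataFrame({"id": [f"v{i}" for i in range(len(p))],
                             "chrom": chrom, "pos": pos, "p": p})

    def test_perfect_ld_pair_yields_single_lead(self, rng):
        g = rng.binomial(2, 0.3, size=300).astype(float)
        G = np.column_stack([g, g])  # r^2 = 1
        tab = self._table([1, 1], [1000, 2000], [1e-10, 1e-9])
        leads = clump_leads(tab, G)
        assert list(leads["id"]) == ["v0"]

    def test_different_chromosomes_both_lead(self, rng):
        g = rng.binomial(2, 0.3, size=300).astype(float)
        G = np.column_stack([g, g])
        tab = self._table([1, 2], [1000, 1000], [1e-10, 1e-9])
        leads = clump_leads(tab, G)
        assert len(leads) == 2

    def test_outside_window_not_claimed(self, rng):
        g = rng.binomial(2, 0.3, size=300).astype(float)
        G = np.column_stack([g, g])
        tab = self._table([1, 1], [1000, 1_000_000], [1e-10, 1e-9])
        assert len(clump_leads(tab, G, window_bp=500_000)) == 2

    def test_no_significant_variants_gives_empty_result(self, rng):
        G = rng.binomial(2, 0.3, size=(100, 3)).astype(float)
        tab = self._table([1, 1, 1], [1, 2, 3], [0.5, 0.2, 0.9])
        assert len(clump_leads(tab, G)) == 0

    def test_deterministic(self, rng):
        G = rng.binomial(2, 0.3, size=(500, 6)).astype(float)
        tab = self._table([1] * 6, np.arange(6) * 1000,
                          [1e-10, 1e-12, 0.5, 1e-9, 0.3, 1e-11])
        l1 = clump_leads(tab, G)
        l2 = clump_leads(tab.copy(), G.copy())
        pd.testing.assert_frame_equal(l1, l2)


class TestPrs:
    def test_single_lead_unit_weight_is_standardized_dosage(self, rng):
        g = rng.binomial(2, 0.3, size=500).astype(float)
        model = build_prs(pd.DataFrame({"id": ["v0"], "beta": [1.0]}))
        scores, dropped = score_prs(model, g[:, None], ["v0"])
        np.testing.assert_allclose(scores, (g - g.mean()) / g.std(), atol=1e-12)
        assert dropped == 0

    def test_absent_lead_dropped_with_warning(self, rng):
        G = rng.binomial(2, 0.3, size=(100, 1)).astype(float)
        model = build_prs(pd.DataFrame({"id": ["v0", "vX"], "beta": [1.0, 2.0]}))
        with pytest.warns(UserWarning):
            _, dropped = score_prs(model, G, ["v0"])
        assert dropped == 1

    def test_duplicate_weights_rejected(self):
        with pytest.raises(GwasError):
            build_prs(pd.DataFrame({"id": ["v0", "v0"], "beta": [1.0, 2.0]}))

    def test_validation_detects_planted_association(self, rng):
        n = 4000
        g = rng.binomial(2, 0.3, size=n).astype(float)
        risk = 0.8 * (g - g.mean()) / g.std()
        y = rng.uniform(size=n) < 1 / (1 + np.exp(-(-1.0 + risk)))
        model = build_prs(pd.DataFrame({"id": ["v0"], "beta": [0.8]}))
        scores, _ = score_prs(model, g[:, None], ["v0"])
        res = validate_prs(scores, pd.DataFrame({"d": y.astype(int)}))
        assert res.loc[0, "p"] < 1e-6 and res.loc[0, "direction"] == 1

    def test_permuted_outcomes_give_null_pvalues(self, rng):
        n = 2000
        g = rng.binomial(2, 0.3, size=n).astype(float)
        y = rng.integers(0, 2, size=n)
        model = build_prs(pd.DataFrame({"id": ["v0"], "beta": [1.0]}))
        scores, _ = score_prs(model, g[:, None], ["v0"])
        ps = []
        for _ in range(40):
            res = validate_prs(scores, pd.DataFrame({"d": rng.permutation(y)}))
            ps.append(res.loc[0, "p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestMetaTableAndQQ:
    def test_meta_analyze_rowwise_matches_meta_fixed(self, rng):
        tabs = []
        for _ in range(2):
            tabs.append(pd.DataFrame({
                "beta": rng.normal(size=5), "se": rng.uniform(0.05, 0.2, 5),
                "p": rng.uniform(size=5), "n": 100,
                "excluded": np.zeros(5, dtype=bool)}))
        out = meta_analyze(tabs)
        for j in range(5):
            b, se, p = meta_fixed([t.loc[j, "beta"] for t in tabs],
                                  [t.loc[j, "se"] for t in tabs])
            assert out.loc[j, "beta"] == pytest.approx(b, abs=1e-12)
            assert out.loc[j, "se"] == pytest.approx(se, abs=1e-12)

    def test_qq_table_is_monotone(self, rng):
        qq = qq_table(rng.uniform(size=500))
        assert (np.diff(qq["observed_neglog10"]) <= 1e-12).all()
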