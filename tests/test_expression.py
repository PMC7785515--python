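"""NB GLM core: filtering, normalisation, dispersion, Wald/LRT, PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from costim import expression as expr
from costim.simulate import SimulationParams, simulate_experiment


def _counts(mat, genes=None, samples=None):
    mat = np.asarray(mat)
    genes = genes or [f"g{i}" for i in range(mat.shape[0])]
    samples = samples or [f"s{j}" for j in range(mat.shape[1])]
    return pd.DataFrame(mat, index=genes, columns=samples)


class TestFilterGenes:
    def _ann(self, genes, chrom="chr1"):
        ann = pd.DataFrame({"gene_id": genes, "chrom": chrom,
                            "start": 0, "end": 1000, "strand": "+"})
        ann["length"] = 1000
        return ann.set_index("gene_id", drop=False)

    def test_threshold_boundary(self):
        c = _counts([[19] * 5, [20, 20, 20, 0, 0], [20, 20, 0, 0, 0]])
        kept = expr.filter_genes(c, self._ann(list(c.index)))
        # 19 everywhere fails the >=20 rule; exactly 3 samples at 20 passes
        assert list(kept.index) == ["g1"]

    def test_sex_chromosome_removed(self):
        c = _counts([[100] * 4, [100] * 4])
        ann = pd.concat([self._ann(["g0"], "chrY"), self._ann(["g1"], "chrX")])
        kept = expr.filter_genes(c, ann)
        assert list(kept.index) == ["g1"]

    def test_all_filtered_raises(self):
        c = _counts([[1, 1, 1]])
        with pytest.raises(ValueError, match="all genes filtered"):
            expr.filter_genes(c, self._ann(["g0"]))


class TestSizeFactors:
    def test_doubled_sample_toy(self):
        c = _counts([[10, 20], [20, 40], [30, 60]])
        s = expr.estimate_size_factors(c)
        assert s.to_numpy() == pytest.approx([1 / np.sqrt(2), np.sqrt(2)])

    def test_single_sample_identity(self):
        s = expr.estimate_size_factors(_counts([[5], [10]]))
        assert s.to_numpy() == pytest.approx([1.0])

    def test_zero_gene_excluded_from_medians(self):
        # gene with a zero drops out of the reference; factors stay finite
        c = _counts([[10, 20], [0, 40], [30, 60]])
        s = expr.estimate_size_factors(c)
        assert np.isfinite(s).all()
        assert s.to_numpy() == pytest.approx([1 / np.sqrt(2), np.sqrt(2)])

    def test_geometric_mean_one(self):
        rng = np.random.default_rng(0)
        c = _counts(rng.integers(1, 500, (50, 8)))
        s = expr.estimate_size_factors(c)
        assert np.exp(np.log(s).mean()) == pytest.approx(1.0, abs=1e-6)

    @given(st.floats(min_value=1.5, max_value=8.0))
    def test_equivariance_under_depth_scaling(self, c_factor):
        rng = np.random.default_rng(1)
        base = rng.integers(1, 300, (40, 4))
        c1 = _counts(base)
        c2 = c1.copy()
        c2["s0"] = np.round(c1["s0"] * c_factor).astype(int)
        s1, s2 = expr.estimate_size_factors(c1), expr.estimate_size_factors(c2)
        ratio = (s2 / s1).to_numpy()
        # sample 0's factor grows by ~c relative to the others (global rescale free)
        assert ratio[0] / ratio[1] == pytest.approx(c_factor, rel=0.15)


class TestDispersions:
    def test_recovery_of_planted_alpha(self):
        rng = np.random.default_rng(2)
        n, alpha = 50, 0.1
        mu = 200.0
        k = 1 / alpha
        mat = rng.negative_binomial(k, k / (k + mu), size=(200, n))
        c = _counts(mat)
        s = pd.Series(1.0, index=c.columns)
        d = expr.estimate_dispersions(c, s, shrink=False)
        assert 0.07 <= d.alpha_mle.median() <= 0.14

    def test_poisson_gene_pinned_at_lower_bound(self):
        rng = np.random.default_rng(3)
        c = _counts(rng.poisson(100, size=(30, 60)))
        s = pd.Series(1.0, index=c.columns)
        d = expr.estimate_dispersions(c, s, shrink=False)
        assert (d.alpha_mle < 1e-3).mean() > 0.5

    def test_infinite_shrinkage_returns_trend(self):
        rng = np.random.default_rng(4)
        k = 1 / 0.2
        c = _counts(rng.negative_binomial(k, k / (k + 100.0), size=(40, 20)))
        s = pd.Series(1.0, index=c.columns)
        tight = expr.estimate_dispersions(c, s, shrink=True, prior_var=1e-8)
        a1, a0 = tight.trend_coef
        mu = (c.to_numpy() / s.to_numpy()).mean(axis=1)
        trend = a1 / mu + a0
        ok = tight.flags == "ok"
        assert np.allclose(tight.alpha[ok], trend[ok.to_numpy()], rtol=1e-2)

    def test_all_zero_gene_flagged(self):
        c = _counts([[0, 0, 0], [10, 12, 9]])
        s = pd.Series(1.0, index=c.columns)
        d = expr.estimate_dispersions(c, s, shrink=False)
        assert d.flags.loc["g0"] == "all_zero" and d.alpha.loc["g0"] == 10.0


class TestNbGlm:
    def test_intercept_only_poisson_limit_is_weighted_mean(self):
        y = np.array([10.0, 20, 30, 40])
        s = np.array([0.5, 1.0, 1.5, 2.0])
        fit = expr.fit_nb_glm(y, np.ones((4, 1)), s, alpha=1e-10)
        # Poisson MLE of the rate with offsets: sum(y)/sum(s)
        assert np.exp(fit.beta[0]) == pytest.approx(y.sum() / s.sum(), rel=1e-6)

    def test_identical_groups_coefficient_zero(self):
        y = np.array([30.0, 30, 30, 30])
        X = np.column_stack([np.ones(4), [0, 0, 1, 1]])
        fit = expr.fit_nb_glm(y, X, np.ones(4), alpha=0.1)
        assert abs(fit.beta[1]) < 1e-4

    def test_full_model_likelihood_dominates_nested(self):
        rng = np.random.default_rng(5)
        y = rng.poisson(50, 12).astype(float)
        X_full = np.column_stack([np.ones(12), rng.normal(size=12)])
        ll_full = expr.fit_nb_glm(y, X_full, np.ones(12), 0.1).loglik
        ll_red = expr.fit_nb_glm(y, X_full[:, :1], np.ones(12), 0.1).loglik
        assert ll_full >= ll_red - 1e-8

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(6), [1, 1, 1, 0, 0, 0], [0, 0, 0, 1, 1, 1]])
        with pytest.raises(expr.DesignError, match="aliased"):
            expr.fit_nb_glm(np.ones(6) * 10, X, np.ones(6), 0.1)

    def test_oracle_against_statsmodels(self):
        # independent fit of the same NB GLM with fixed alpha
        import statsmodels.api as sm

        rng = np.random.default_rng(6)
        X = np.column_stack([np.ones(40), rng.integers(0, 3, 40).astype(float)])
        mu = np.exp(3.0 + 0.5 * X[:, 1])
        k = 1 / 0.1
        y = rng.negative_binomial(k, k / (k + mu)).astype(float)
        fit = expr.fit_nb_glm(y, X, np.ones(40), alpha=0.1)
        ref = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=0.1)).fit()
        assert fit.beta == pytest.approx(ref.params, abs=1e-4)
        assert fit.se == pytest.approx(ref.bse, rel=1e-3)


class TestLrt:
    def test_identical_designs_give_zero(self):
        c = _counts([[10, 12, 9, 11]])
        X = np.ones((4, 1))
        res = expr.lrt_test(c, X, X, np.ones(4), np.array([0.1]))
        assert res["stat"].iloc[0] == pytest.approx(0.0, abs=1e-8)
        assert res["p"].iloc[0] == 1.0

    def test_non_nested_rejected(self):
        c = _counts([[10, 12, 9, 11]])
        X_full = np.column_stack([np.ones(4), [0, 0, 1, 1]])
        X_red = np.array([[1.0], [2], [4], [8]])
        with pytest.raises(expr.DesignError, match="nested"):
            expr.lrt_test(c, X_full, X_red, np.ones(4), np.array([0.1]))

    def test_planted_dose_effect_detected(self):
        rng = np.random.default_rng(7)
        dose = np.tile([0, 1, 2], 4).astype(float)
        mu = 100 * 2.0 ** dose
        k = 1 / 0.05
        mat = rng.negative_binomial(k, k / (k + mu), size=(50, 12))
        c = _counts(mat)
        X_full = np.column_stack([np.ones(12), dose])
        res = expr.lrt_test(c, X_full, X_full[:, :1], np.ones(12),
                            np.full(50, 0.05))
        assert np.median(res["p"]) < 1e-3

    def test_wald_and_lrt_agree_at_large_n(self):
        # same dose coefficient tested two ways on 210-sample simulations
        p = SimulationParams(class_counts={"cd28_linear": 30, "null": 30},
                             n_donors=30, batch_effect_sd=0.0, seed=17)
        sim = simulate_experiment(p)
        d = sim.design[sim.design["cell_type"] == "naive"]
        c = sim.counts[d.index].iloc[:60]
        s = pd.Series(1.0, index=d.index)
        dose = d["cd28_dose"].astype(float).to_numpy()
        X = np.column_stack([np.ones(len(d)), dose])
        alphas = np.full(60, 0.1)
        wald_p = []
        for g in range(60):
            fit = expr.fit_nb_glm(c.iloc[g].to_numpy(), X, s.to_numpy(), 0.1)
            z = fit.beta[1] / fit.se[1]
            wald_p.append(2 * stats.norm.sf(abs(z)))
        lrt = expr.lrt_test(c, X, X[:, :1], s.to_numpy(), alphas)
        rho = stats.spearmanr(wald_p, lrt["p"]).statistic
        assert rho > 0.95


class TestWaldDe:
    def test_null_data_gives_large_q_and_no_calls(self):
        sim = simulate_experiment(SimulationParams(
            class_counts={"null": 200}, dispersion_sd_log=0.0, seed=13))
        sf = expr.estimate_size_factors(sim.counts)
        alphas = pd.Series(0.1, index=sim.counts.index)
        res = expr.wald_de_test(sim.counts, sim.design, sf, alphas,
                                "naive", "lowTCR_lowCD28")
        assert res["q"].min() > 0.2
        assert not res["upregulated"].any()

    def test_small_group_rejected(self, small_sim):
        sim = small_sim
        design = sim.design.iloc[:3]  # not 2 per group
        sf = expr.estimate_size_factors(sim.counts)
        with pytest.raises(ValueError, match="< 2 samples"):
            expr.wald_de_test(sim.counts, design, sf,
                              pd.Series(0.1, index=sim.counts.index),
                              "naive", "highCD28")

    def test_bh_mapping_invariant_to_gene_order(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=100)
        q = expr.bh_adjust(p)
        perm = rng.permutation(100)
        q_perm = expr.bh_adjust(p[perm])
        assert q_perm == pytest.approx(q[perm])


class TestVarianceAndPca:
    def test_pure_factor_signal_explains_everything(self):
        design = pd.DataFrame({"cell_type": ["naive"] * 3 + ["memory"] * 3,
                               "donor": list("abcabc")},
                              index=[f"s{i}" for i in range(6)])
        base = np.array([[1, 1, 1, 5, 5, 5], [2, 2, 2, 9, 9, 9]], dtype=float)
        ln = pd.DataFrame(base, index=["g0", "g1"], columns=design.index)
        assert expr.variance_explained(ln, design, "cell_type") == pytest.approx(1.0)
        assert expr.variance_explained(ln, design, "donor") == pytest.approx(0.0, abs=1e-12)

    def test_noise_r2_matches_expectation(self):
        rng = np.random.default_rng(9)
        n, levels = 40, 4
        design = pd.DataFrame({"grp": np.repeat(list("abcd"), n // levels)},
                              index=[f"s{i}" for i in range(n)])
        ln = pd.DataFrame(rng.normal(size=(500, n)), columns=design.index)
        r2 = expr.variance_explained(ln, design, "grp")
        assert r2 == pytest.approx((levels - 1) / (n - 1), abs=0.015)

    def test_single_level_factor_rejected(self):
        design = pd.DataFrame({"grp": ["a", "a", "a"]}, index=["s0", "s1", "s2"])
        ln = pd.DataFrame(np.ones((2, 3)), columns=design.index)
        with pytest.raises(ValueError, match="fewer than 2 levels"):
            expr.variance_explained(ln, design, "grp")

    def test_duplicated_samples_share_scores(self):
        rng = np.random.default_rng(10)
        ln = pd.DataFrame(rng.normal(size=(30, 4)),
                          columns=["s0", "s1", "s2", "s3"])
        ln["s3"] = ln["s2"]
        scores, frac = expr.pca(ln)
        assert scores.loc["s2"].to_numpy() == pytest.approx(
            scores.loc["s3"].to_numpy(), abs=1e-8)
        assert np.all(np.diff(frac) <= 1e-12)
        assert frac.sum() <= 1.0 + 1e-9

    def test_planted_clusters_separate_on_pc1(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0, 0.1, size=(100, 5))
        b = rng.normal(3, 0.1, size=(100, 5))
        ln = pd.DataFrame(np.hstack([a, b]),
                          columns=[f"s{i}" for i in range(10)])
        scores, _ = expr.pca(ln)
        pc1 = scores["PC1"]
        between = abs(pc1[:5].mean() - pc1[5:].mean())
        within = max(pc1[:5].std(), pc1[5:].std())
        assert between / within >= 10

    def test_too_few_samples(self):
        ln = pd.DataFrame(np.ones((5, 2)), columns=["a", "b"])
        with pytest.raises(ValueError, match="3 samples"):
            expr.pca(ln)
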