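"""Per-gene P-values, combination methods and subject-sampling significance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gsabench as gb
from gsabench.genelevel import (
    CombinationSpec,
    combine_pvalues,
    gene_pvalues,
    genelevel_test_collection,
    geneset_pvalue_subject_sampling,
)
from gsabench.selfcontained import TestConfig
from gsabench.simulate import CountDataset, GeneSetCollection


class TestGenePvalues:
    def test_identical_groups_give_p_one(self):
        X = np.array([[1.0, 2.0, 3.0], [5.0, 5.0, 7.0]])
        assert gene_pvalues(X, X.copy()) == pytest.approx([1.0, 1.0])

    def test_constant_gene_convention(self):
        X = np.array([[2.0, 2.0], [1.0, 2.0]])
        Y = np.array([[2.0, 2.0], [1.5, 2.5]])
        assert gene_pvalues(X, Y)[0] == 1.0

    @pytest.mark.parametrize("test", ["welch_t", "moderated_t"])
    def test_uniform_under_normal_null(self, rng, test):
        # Kolmogorov distance from U(0,1) below 0.02 at 10^4 genes
        X = rng.normal(size=(10_000, 10))
        Y = rng.normal(size=(10_000, 10))
        p = gene_pvalues(X, Y, test=test)
        grid = np.sort(p)
        ks = np.max(np.abs(grid - np.arange(1, p.size + 1) / p.size))
        assert ks < 0.02

    def test_large_shift_is_significant(self, rng):
        # 5 SD mean shift at n1 = n2 = 10 pushes far into the t tail
        X = rng.normal(size=(1, 10))
        Y = rng.normal(loc=5.0, size=(1, 10))
        assert gene_pvalues(X, Y)[0] < 1e-3

    def test_unknown_test_rejected(self, rng):
        with pytest.raises(ValueError):
            gene_pvalues(rng.normal(size=(2, 4)), rng.normal(size=(2, 4)), test="z")


class TestCombine:
    def test_fisher_all_ones_is_zero(self):
        assert combine_pvalues(np.ones(5), CombinationSpec("FM")) == pytest.approx(0.0)

    def test_fisher_half_half(self):
        # -2 * 2 * ln(0.5) = 2.7726
        stat = combine_pvalues(np.array([0.5, 0.5]), CombinationSpec("FM"))
        assert stat == pytest.approx(2.7726, abs=1e-4)

    def test_stouffer_symmetric_pair_cancels(self):
        stat = combine_pvalues(np.array([0.1, 0.9]), CombinationSpec("SM"))
        assert stat == pytest.approx(0.0, abs=1e-9)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(min_value=1e-8, max_value=0.999), min_size=1, max_size=20)
    )
    def test_gamma_shape_one_equals_half_fisher(self, pvals):
        # Q_gamma(1-p; 1, 1) = -ln p, the exponential quantile
        p = np.array(pvals)
        gm = combine_pvalues(p, CombinationSpec("GM", gm_shape=1.0))
        fm = combine_pvalues(p, CombinationSpec("FM"))
        assert gm == pytest.approx(fm / 2.0, rel=1e-9)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=2, max_size=10),
        st.integers(min_value=0, max_value=9),
        st.floats(min_value=0.1, max_value=0.9),
    )
    def test_fisher_monotone_in_each_pvalue(self, pvals, pos, factor):
        # shrinking any single P-value can only increase the FM score
        p = np.array(pvals)
        i = pos % p.size
        smaller = p.copy()
        smaller[i] *= factor
        assert combine_pvalues(smaller, CombinationSpec("FM")) >= combine_pvalues(
            p, CombinationSpec("FM")
        )

    def test_zero_pvalue_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            stat = combine_pvalues(np.array([0.0, 0.5]), CombinationSpec("FM"))
        assert np.isfinite(stat)

    def test_validation(self):
        with pytest.raises(ValueError):
            combine_pvalues(np.array([0.5, 1.5]), CombinationSpec("FM"))
        with pytest.raises(ValueError):
            CombinationSpec("GM", gm_shape=0.0)
        with pytest.raises(ValueError):
            CombinationSpec("XX")


class TestSubjectSampling:
    def test_strong_signal_hits_permutation_floor(self, pool):
        design = gb.SimulationDesign(N=20, p=8, S=4, beta=0.25, gamma=1.0, fc=3.0)
        ds, sets = gb.simulate_power_dataset(pool, design, seed=31)
        cfg = TestConfig(n_perm=199, seed=32)
        res = geneset_pvalue_subject_sampling(
            ds, sets.sets[sets.de_names()[0]], config=cfg
        )
        assert res.p_value == pytest.approx(1.0 / 200.0)

    def test_single_set_matches_collection_runner(self, null_dataset):
        ds, sets = null_dataset
        cfg = TestConfig(seed=5)
        batch = genelevel_test_collection(ds, sets, cfg).set_index("set_name")
        name = sets.names()[0]
        single = geneset_pvalue_subject_sampling(ds, sets.sets[name], config=cfg)
        assert single.statistic == pytest.approx(batch.loc[name, "statistic"])
        assert single.p_value == pytest.approx(batch.loc[name, "p_value"])

    @pytest.mark.parametrize("method", ["sm", "gm"])
    def test_alternative_combiners_run_and_stay_in_range(self, null_dataset, method):
        ds, sets = null_dataset
        res = gb.get_method(method)(ds, sets, TestConfig(seed=13))
        assert len(res) == len(sets)
        assert ((res["p_value"] > 0) & (res["p_value"] <= 1)).all()
        assert np.isfinite(res["statistic"]).all()

    def test_fm_vs_sm_agree_in_direction_but_not_identically(self, pool):
        from scipy.stats import spearmanr

        design = gb.SimulationDesign(N=10, p=8, S=60, beta=0.5, gamma=0.5, fc=2.0)
        ds, sets = gb.simulate_power_dataset(pool, design, seed=41)
        cfg = TestConfig(seed=42)
        fm = gb.get_method("fm")(ds, sets, cfg)["p_value"].to_numpy()
        sm = gb.get_method("sm")(ds, sets, cfg)["p_value"].to_numpy()
        rho = spearmanr(fm, sm).statistic
        assert rho > 0.5
        assert not np.allclose(fm, sm)

    def test_calibrated_under_correlated_genes(self):
        # genes within a set share a latent log-normal factor, inducing
        # strong positive correlation; subject sampling must stay near the
        # nominal level anyway (the motivation for permutation over the
        # chi-square null for FM)
        rng = np.random.default_rng(77)
        S, p, N = 400, 8, 10
        factor = np.repeat(rng.normal(scale=0.5, size=(S, 1, N)), p, axis=1)
        rate = np.exp(np.log(50.0) + 0.8 * factor).reshape(S * p, N)
        counts = rng.poisson(rate)
        ds = CountDataset(
            counts,
            [f"g{i}" for i in range(S * p)],
            np.full(S * p, 1000),
            [1] * (N // 2) + [2] * (N // 2),
        )
        sets = GeneSetCollection(
            {f"s{k}": [f"g{i}" for i in range(k * p, (k + 1) * p)] for k in range(S)}
        )
        res = genelevel_test_collection(ds, sets, TestConfig(seed=78))
        rate_detected = float((res["p_value"] < 0.05).mean())
        assert abs(rate_detected - 0.05) < 3 * np.sqrt(0.05 * 0.95 / S)

    def test_chi2_asymptotic_fisher_matches_independent_uniform_theory(self):
        from gsabench.genelevel import fisher_asymptotic_pvalue

        # one P-value: FM = -2 ln p, chi2(2) survival gives back p exactly
        p = 0.037
        stat = combine_pvalues(np.array([p]), CombinationSpec("FM"))
        assert fisher_asymptotic_pvalue(stat, 1) == pytest.approx(p, rel=1e-9)
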