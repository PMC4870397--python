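"""Self-contained multivariate statistics, MST ranking and permutation engine."""

import numpy as np
import pytest

import gsabench as gb
from gsabench._perm import n_distinct_splits, split_masks
from gsabench.normalize import log_cpm, rpkm
from gsabench.selfcontained import (
    TestConfig,
    _pairwise_distances,
    mst_ks_stat,
    mst_ranking,
    mst_total_weight,
    mstks_test_collection,
    n_stat,
    nstat_test_collection,
    permutation_pvalue,
    sam_gs_stat,
    samgs_test_collection,
)


from _oracles import brute_force_n_stat, networkx_mst_weight


class TestSamGS:
    def test_equal_means_give_zero(self):
        X = np.array([[1.0, 3.0], [4.0, 6.0]])
        Y = np.array([[3.0, 1.0], [5.0, 5.0]])
        assert sam_gs_stat(X, Y, s0=0.5) == pytest.approx(0.0)

    def test_hand_computed_single_gene(self):
        # x=(1,3), y=(5,7): pooled SD = sqrt(2), t = -4/sqrt(2), T = 8
        assert sam_gs_stat([[1.0, 3.0]], [[5.0, 7.0]], s0=0.0) == pytest.approx(8.0)

    def test_additivity_over_genes(self):
        X = np.array([[1.0, 3.0], [2.0, 4.0]])
        Y = np.array([[5.0, 7.0], [3.0, 3.0]])
        t = sam_gs_stat(X, Y, s0=0.1)
        # appending a gene with equal group means leaves T unchanged
        X2 = np.vstack([X, [1.0, 5.0]])
        Y2 = np.vstack([Y, [2.0, 4.0]])
        assert sam_gs_stat(X2, Y2, s0=0.1) == pytest.approx(t)

    def test_shift_invariance_per_gene(self, rng):
        X = rng.normal(size=(4, 5))
        Y = rng.normal(size=(4, 6))
        t = sam_gs_stat(X, Y, s0=0.2)
        X2, Y2 = X.copy(), Y.copy()
        X2[2] += 17.0
        Y2[2] += 17.0
        assert sam_gs_stat(X2, Y2, s0=0.2) == pytest.approx(t)

    def test_zero_pooled_sd_with_zero_s0_errors(self):
        with pytest.raises(ValueError, match="s0"):
            sam_gs_stat([[1.0, 1.0]], [[1.0, 1.0]], s0=0.0)


class TestNStat:
    def test_identical_singletons_are_zero(self):
        x = np.array([[1.0], [2.0]])
        assert n_stat(x, x.copy()) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        # X=(0,0), Y=(3,4): 0.5 * sqrt(5)
        assert n_stat([[0.0], [0.0]], [[3.0], [4.0]]) == pytest.approx(0.5 * np.sqrt(5))

    def test_symmetric_and_nonnegative(self, rng):
        X = rng.normal(size=(3, 4))
        Y = rng.normal(size=(3, 6))
        assert n_stat(X, Y) >= 0.0
        assert n_stat(X, Y) == pytest.approx(n_stat(Y, X))

    def test_matches_brute_force_double_loop(self, rng):
        for _ in range(100):
            X = rng.normal(size=(5, 5))
            Y = rng.normal(size=(5, 5)) + rng.normal(scale=0.5)
            assert abs(n_stat(X, Y) - brute_force_n_stat(X, Y)) < 1e-10


class TestMST:
    def test_total_weight_matches_networkx(self, rng):
        pytest.importorskip("networkx")
        for n in range(3, 9):
            pts = rng.normal(size=(3, n))
            D = _pairwise_distances(pts)
            assert mst_total_weight(D) == pytest.approx(networkx_mst_weight(D), abs=1e-10)

    def test_collinear_path_hand_case(self):
        # points 1,2,3,4 on a line, first two vs last two: D = 1.0
        X = np.array([[1.0, 2.0]])
        Y = np.array([[3.0, 4.0]])
        assert mst_ks_stat(X, Y) == pytest.approx(1.0)

    def test_interleaved_labels_score_low(self):
        # alternating groups along a path cannot separate
        pts = np.arange(8.0)[None, :]
        X = pts[:, ::2]
        Y = pts[:, 1::2]
        assert mst_ks_stat(X, Y) <= 0.5

    def test_isometry_invariance(self, rng):
        X = rng.normal(size=(4, 6))
        Y = rng.normal(size=(4, 5)) + 0.3
        base = mst_ks_stat(X, Y)
        Q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        shift = rng.normal(size=(4, 1))
        assert mst_ks_stat(Q @ X + shift, Q @ Y + shift) == pytest.approx(base)

    def test_duplicate_points_are_handled(self):
        X = np.array([[0.0, 0.0, 1.0]])
        Y = np.array([[0.0, 1.0, 2.0]])
        s = mst_ks_stat(X, Y)
        assert 0.0 <= s <= 1.0

    def test_ranking_is_a_permutation(self, rng):
        pts = rng.normal(size=(2, 7))
        order = mst_ranking(_pairwise_distances(pts))
        assert sorted(order.tolist()) == list(range(7))


class TestPermutationEngine:
    def test_exhaustive_split_count_balanced_ten(self):
        labels = np.array([1] * 5 + [2] * 5)
        masks, exhaustive = split_masks(labels, TestConfig(seed=0))
        assert exhaustive
        assert masks.shape == (127, 10)  # observed + C(10,5)/2 = 126 splits
        assert n_distinct_splits(5, 5) == 126

    def test_observed_max_gives_pvalue_floor(self, rng):
        # continuous data with huge separation: observed statistic beats all
        # B = 99 random permutations -> p = 1/(1+99)
        values = np.vstack([rng.normal(size=20), rng.normal(size=20)])
        values[:, 10:] += 100.0
        labels = np.array([1] * 10 + [2] * 10)
        cfg = TestConfig(n_perm=99, exhaustive_threshold=2, seed=4)
        res = permutation_pvalue(n_stat, values, labels, cfg)
        assert res.p_value == pytest.approx(0.01)
        assert res.n_perm_used == 99

    def test_exhaustive_pvalues_are_fractions_of_126(self, null_dataset):
        ds, sets = null_dataset
        res = nstat_test_collection(ds, sets, TestConfig(seed=0))
        assert (res["n_perm"] == 126).all()
        assert np.allclose(np.round(res["p_value"] * 126), res["p_value"] * 126)

    def test_generic_engine_matches_batch_runner(self, null_dataset):
        ds, sets = null_dataset
        cfg = TestConfig(seed=0)
        batch = nstat_test_collection(ds, sets, cfg)
        expr = rpkm(ds).values
        name = sets.names()[2]
        idx = ds.gene_indices(sets.sets[name])
        single = permutation_pvalue(n_stat, expr[idx], ds.labels, cfg)
        row = batch[batch.set_name == name].iloc[0]
        assert single.statistic == pytest.approx(row.statistic)
        assert single.p_value == pytest.approx(row.p_value)


class TestBatchRunnersMatchStatistics:
    """The vectorised whole-collection runners must reproduce the plain
    per-set statistics exactly."""

    def test_nstat(self, null_dataset):
        ds, sets = null_dataset
        expr = rpkm(ds).values
        res = nstat_test_collection(ds, sets, TestConfig(seed=0)).set_index("set_name")
        g1 = ds.labels == 1
        for name in sets.names():
            idx = ds.gene_indices(sets.sets[name])
            expected = n_stat(expr[idx][:, g1], expr[idx][:, ~g1])
            assert res.loc[name, "statistic"] == pytest.approx(expected, abs=1e-12)

    def test_mstks(self, null_dataset):
        ds, sets = null_dataset
        expr = rpkm(ds).values
        res = mstks_test_collection(ds, sets, TestConfig(seed=0)).set_index("set_name")
        g1 = ds.labels == 1
        for name in sets.names():
            idx = ds.gene_indices(sets.sets[name])
            expected = mst_ks_stat(expr[idx][:, g1], expr[idx][:, ~g1])
            assert res.loc[name, "statistic"] == pytest.approx(expected, abs=1e-12)

    def test_samgs(self, null_dataset):
        ds, sets = null_dataset
        E = log_cpm(ds).values
        g1 = ds.labels == 1
        cfg = TestConfig(seed=0, s0_policy="fixed:0.3")
        res = samgs_test_collection(ds, sets, cfg).set_index("set_name")
        for name in sets.names():
            idx = ds.gene_indices(sets.sets[name])
            expected = sam_gs_stat(E[idx][:, g1], E[idx][:, ~g1], s0=0.3)
            assert res.loc[name, "statistic"] == pytest.approx(expected, abs=1e-10)


@pytest.fixture(scope="module")
def h0_results(pool):
    ds, sets = gb.simulate_null_dataset(pool, N=10, p=8, S=2000, seed=21)
    cfg = TestConfig(seed=22)
    return {
        m: gb.get_method(m)(ds, sets, cfg)["p_value"].to_numpy()
        for m in ("nstat", "samgs", "mstks")
    }


class TestNullCalibration:
    """Permutation tests attain (or respect) the nominal level on H0 data."""

    @pytest.mark.parametrize("method", ["nstat", "samgs"])
    def test_continuous_statistics_calibrated(self, h0_results, method):
        rate = float((h0_results[method] < 0.05).mean())
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 2000)

    def test_mstks_is_valid_but_conservative(self, h0_results):
        # the KS statistic is heavily tied at small N, so its exact
        # permutation test detects below the nominal level, never above
        rate = float((h0_results["mstks"] < 0.05).mean())
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 2000)
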