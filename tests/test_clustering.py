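import itertools

import numpy as np
import pytest
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

import ildtax as it
from ildtax.clustering import DistanceMatrix


def brute_force_cophenetic(tree):
    """Replay the merges with explicit member sets; cophenetic distance of a
    pair is the height of the first merge that unites them."""
    n = tree.n
    members = {i: {i} for i in range(n)}
    coph = np.zeros((n, n))
    for step, (left, right, h, _s) in enumerate(tree.merges):
        a, b = members[int(left)], members[int(right)]
        for i in a:
            for j in b:
                coph[i, j] = coph[j, i] = h
        members[n + step] = a | b
    return squareform(coph)


def minimax_path_distances(square_d):
    """Bottleneck (minimax-edge) path distances by repeated relaxation."""
    mm = square_d.copy()
    n = mm.shape[0]
    for _ in range(n):
        for k in range(n):
            mm = np.minimum(mm, np.maximum(mm[:, k][:, None], mm[k][None, :]))
    np.fill_diagonal(mm, 0)
    return mm


@pytest.fixture(scope="module")
def scores(survey):
    ds, _ = survey
    res = it.fit_pca(it.normalize(ds, "utpm"))
    return it.project(res, 3).T


class TestPairwiseDistances:
    def test_euclidean_and_cityblock_worked_example(self):
        x = np.array([[0.0, 0.0], [3.0, 4.0]])
        assert it.pairwise_distances(x, "euclidean").condensed[0] == pytest.approx(5.0)
        assert it.pairwise_distances(x, "cityblock").condensed[0] == pytest.approx(7.0)

    def test_cosine_of_positive_multiple_is_zero(self):
        x = np.array([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0]])
        assert it.pairwise_distances(x, "cosine").condensed[0] == pytest.approx(0.0, abs=1e-12)

    def test_cosine_rejects_zero_norm_row(self):
        x = np.array([[1.0, 1.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="row 1"):
            it.pairwise_distances(x, "cosine")

    def test_mahalanobis_on_whitened_data_equals_euclidean(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(40, 3))
        x = (x - x.mean(0)) / x.std(0, ddof=1)
        # decorrelate exactly so the sample covariance is the identity
        cov = np.cov(x.T)
        L = np.linalg.cholesky(np.linalg.inv(cov))
        xw = x @ L
        m = it.pairwise_distances(xw, "mahalanobis").condensed
        e = it.pairwise_distances(xw, "euclidean").condensed
        np.testing.assert_allclose(m, e, atol=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_minkowski_p2_matches_double_loop_euclidean_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(9, 4))
        mink = it.pairwise_distances(x, "minkowski", p=2).condensed
        oracle = [
            np.sqrt(np.sum((x[i] - x[j]) ** 2))
            for i in range(9)
            for j in range(i + 1, 9)
        ]
        np.testing.assert_allclose(mink, oracle, rtol=1e-12)

    def test_seuclidean_standardizes_by_unbiased_variance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(6, 3)) * np.array([1.0, 10.0, 0.1])
        v = x.var(axis=0, ddof=1)
        se = it.pairwise_distances(x, "seuclidean").condensed
        oracle = [
            np.sqrt(np.sum((x[i] - x[j]) ** 2 / v))
            for i in range(6)
            for j in range(i + 1, 6)
        ]
        np.testing.assert_allclose(se, oracle, rtol=1e-12)

    def test_singular_covariance_warns_and_uses_pinv(self):
        x = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])  # rank-1 columns
        with pytest.warns(UserWarning, match="pseudo-inverse"):
            it.pairwise_distances(x, "mahalanobis")


class TestLinkage:
    def test_three_point_single_linkage_worked_example(self):
        dm = DistanceMatrix(np.array([1.0, 2.0, 3.0]), "euclidean", n=3)
        tree = it.linkage(dm, "single")
        assert {int(tree.merges[0, 0]), int(tree.merges[0, 1])} == {0, 1}
        np.testing.assert_allclose(tree.heights, [1.0, 2.0])

    def test_208_rows_give_207_merges(self, scores):
        dm = it.pairwise_distances(scores, "cosine")
        tree = it.linkage(dm, "ward")
        assert tree.merges.shape[0] == 207
        assert int(tree.merges[-1, 3]) == 208

    @pytest.mark.parametrize("method", it.LINKAGES)
    def test_heights_non_decreasing(self, method):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(30, 4))
        tree = it.linkage(it.pairwise_distances(x, "euclidean"), method)
        assert np.all(np.diff(tree.heights) >= -1e-12)

    def test_single_item_rejected(self):
        with pytest.raises(ValueError):
            it.linkage(DistanceMatrix(np.empty(0), "euclidean", n=1), "single")


class TestCophenetic:
    def test_ultrametric_triple_has_ccc_one(self):
        # isoceles triple d(a,b)=1, d(a,c)=d(b,c)=2 is already ultrametric
        dm = DistanceMatrix(np.array([1.0, 2.0, 2.0]), "euclidean", n=3)
        tree = it.linkage(dm, "average")
        ccc, coph = it.cophenetic(tree, dm)
        assert ccc == pytest.approx(1.0)
        np.testing.assert_allclose(coph, dm.condensed)

    def test_zero_variance_distances_flagged(self):
        dm = DistanceMatrix(np.ones(3), "euclidean", n=3)
        tree = it.linkage(dm, "single")
        with pytest.raises(ValueError, match="undefined"):
            it.cophenetic(tree, dm)

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("method", it.LINKAGES)
    def test_matches_lowest_common_merge_oracle(self, seed, method):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 9)
        x = rng.normal(size=(n, 3))
        dm = it.pairwise_distances(x, "euclidean")
        tree = it.linkage(dm, method)
        ccc, coph = it.cophenetic(tree, dm)
        oracle = brute_force_cophenetic(tree)
        np.testing.assert_allclose(coph, oracle, rtol=1e-12)
        expected_ccc = np.corrcoef(dm.condensed, oracle)[0, 1]
        assert ccc == pytest.approx(expected_ccc, abs=1e-12)
        assert -1.0 <= ccc <= 1.0

    @pytest.mark.parametrize("seed", range(4))
    def test_cophenetic_distances_are_ultrametric(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(8, 3))
        dm = it.pairwise_distances(x, "euclidean")
        tree = it.linkage(dm, "average")
        _, coph = it.cophenetic(tree, dm)
        c = squareform(coph)
        for a, b, d in itertools.permutations(range(8), 3):
            assert c[a, d] <= max(c[a, b], c[b, d]) + 1e-12

    @pytest.mark.parametrize("seed", range(4))
    def test_single_linkage_equals_minimax_path_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        x = rng.normal(size=(8, 3))
        dm = it.pairwise_distances(x, "euclidean")
        tree = it.linkage(dm, "single")
        _, coph = it.cophenetic(tree, dm)
        oracle = minimax_path_distances(dm.square())
        np.testing.assert_allclose(squareform(coph), oracle, rtol=1e-10)


class TestCCCGrid:
    def test_grid_shape_bounds_and_argmax(self, scores):
        grid = it.ccc_grid(scores)
        assert grid.values.shape == (6, 4)
        finite = grid.values[np.isfinite(grid.values)]
        assert np.all(finite >= -1.0) and np.all(finite <= 1.0)
        best_val = grid.value(*grid.best)
        assert best_val == pytest.approx(np.nanmax(grid.values))

    def test_single_combination_equals_direct_cophenetic(self, scores):
        grid = it.ccc_grid(scores, metrics=("cosine",), linkages=("ward",))
        dm = it.pairwise_distances(scores, "cosine")
        ccc, _ = it.cophenetic(it.linkage(dm, "ward"), dm)
        assert grid.values.shape == (1, 1)
        assert grid.value("cosine", "ward") == pytest.approx(ccc)

    def test_argmax_stable_under_row_permutation(self, scores):
        rng = np.random.default_rng(0)
        perm = rng.permutation(scores.shape[0])
        a = it.ccc_grid(scores)
        b = it.ccc_grid(scores[perm])
        assert a.best == b.best
        np.testing.assert_allclose(a.values, b.values, atol=1e-10)


class TestInconsistency:
    def test_equal_height_tree_all_zero(self):
        x = np.arange(5.0)[:, None]
        dm = DistanceMatrix(np.ones(10), "euclidean", n=5)
        tree = it.linkage(dm, "single")
        table = it.inconsistency(tree, depth=3)
        np.testing.assert_array_equal(table.coefficients, 0.0)

    def test_leaf_only_merge_is_zero(self, scores):
        dm = it.pairwise_distances(scores, "cosine")
        tree = it.linkage(dm, "ward")
        table = it.inconsistency(tree, depth=3)
        # merges joining two singletons have a one-link window
        leaf_merges = (tree.merges[:, 0] < tree.n) & (tree.merges[:, 1] < tree.n)
        assert np.all(table.coefficients[leaf_merges] == 0.0)

    def test_four_point_tree_matches_hand_computation(self):
        # points on a line at 0, 1, 10, 12 -> single linkage merges:
        # (0,1)@1, (10,12)@2, join@9
        x = np.array([[0.0], [1.0], [10.0], [12.0]])
        dm = it.pairwise_distances(x, "euclidean")
        tree = it.linkage(dm, "single")
        table = it.inconsistency(tree, depth=2).table
        # root window holds heights {9, 1, 2}
        hs = np.array([9.0, 1.0, 2.0])
        expected = (9.0 - hs.mean()) / hs.std(ddof=1)
        assert table[2, 3] == pytest.approx(expected)
        assert table[0, 3] == 0.0 and table[1, 3] == 0.0

    def test_depth_must_be_positive(self, scores):
        dm = it.pairwise_distances(scores, "cosine")
        tree = it.linkage(dm, "ward")
        with pytest.raises(ValueError):
            it.inconsistency(tree, depth=0)


@pytest.fixture(scope="module")
def tree(scores):
    dm = it.pairwise_distances(scores, "cosine")
    return it.linkage(dm, "ward")


class TestCut:

    def test_k_equals_n_gives_singletons(self, tree):
        sol = it.cut(tree, k=tree.n)
        assert sol.k == tree.n
        np.testing.assert_array_equal(np.sort(np.unique(sol.labels)), np.arange(1, tree.n + 1))

    def test_k_equals_one(self, tree):
        sol = it.cut(tree, k=1)
        assert sol.k == 1 and np.all(sol.labels == 1)

    @pytest.mark.parametrize("k", [2, 5, 7, 50])
    def test_exactly_k_nonempty_clusters(self, tree, k):
        sol = it.cut(tree, k=k)
        assert sol.k == k
        assert np.all(sol.counts > 0) and sol.counts.sum() == tree.n

    def test_inconsistency_threshold_cut(self, tree):
        sol = it.cut(tree, inconsistency_threshold=1.15, depth=3)
        assert 1 <= sol.k <= tree.n
        assert sol.counts.sum() == tree.n

    def test_exactly_one_criterion_required(self, tree):
        with pytest.raises(ValueError):
            it.cut(tree)
        with pytest.raises(ValueError):
            it.cut(tree, k=3, inconsistency_threshold=1.0)

    def test_labels_invariant_under_row_permutation(self, scores):
        rng = np.random.default_rng(4)
        perm = rng.permutation(scores.shape[0])
        def solve(x):
            dm = it.pairwise_distances(x, "cosine")
            return it.cut(it.linkage(dm, "ward"), k=7).labels
        a = solve(scores)
        b = np.empty_like(a)
        b[perm] = solve(scores[perm])
        assert adjusted_rand_score(a, b) == pytest.approx(1.0)
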