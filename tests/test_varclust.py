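import itertools

import numpy as np
import pytest

from blocksurv.io import standardize
from blocksurv.varclust import (VariableClustering, _lambda1, _power_lambda1, agglomerate,
                                cluster_homogeneity, cut_tree, dissimilarity,
                                suggest_block_count)
from blocksurv.synthetic import SyntheticConfig, generate_multiomics

from conftest import make_matrix, std_matrix


def brute_force_agglomeration(X):
    """Independent oracle: recompute every candidate dissimilarity by dense
    eigendecomposition at every step, same tie-break as the implementation."""
    n, p = X.shape
    corr = X.T @ X / (n - 1)

    def lam1(ix):
        if len(ix) == 1:
            return 1.0
        sub = corr[np.ix_(list(ix), list(ix))]
        return float(np.linalg.eigvalsh(sub)[-1])

    clusters = [(i,) for i in range(p)]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            ca, cb = clusters[a], clusters[b]
            d = lam1(ca) + lam1(cb) - lam1(tuple(sorted(ca + cb)))
            key = (min(ca[0], cb[0]), max(ca[0], cb[0]))
            if (best is None or d < best[0] - 1e-12
                    or (abs(d - best[0]) <= 1e-12 and key < best[1])):
                best = (d, key, a, b)
        d, _, a, b = best
        merged = tuple(sorted(clusters[a] + clusters[b]))
        merges.append((frozenset(clusters[a]), frozenset(clusters[b]), d))
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)] + [merged]
    return merges


class TestClusterHomogeneity:
    def test_single_variable_is_one(self, rng):
        m = std_matrix(rng.standard_normal((30, 1)))
        lam, scores = cluster_homogeneity(m.values)
        assert lam == pytest.approx(1.0)
        np.testing.assert_allclose(scores, m.values[:, 0])

    def test_two_variables_equals_one_plus_r(self, rng):
        X = std_matrix(rng.standard_normal((50, 2))).values
        r = float(np.corrcoef(X.T)[0, 1])
        lam, _ = cluster_homogeneity(X)
        assert lam == pytest.approx(1 + abs(r), abs=1e-10)

    def test_three_exact_copies_give_three(self, rng):
        x = rng.standard_normal(40)
        m = std_matrix(np.column_stack([x, x, x]))
        lam, _ = cluster_homogeneity(m.values)
        assert lam == pytest.approx(3.0, abs=1e-10)

    def test_squared_correlations_sum_to_lambda1(self, rng):
        X = std_matrix(rng.standard_normal((60, 5))).values
        lam, scores = cluster_homogeneity(X)
        rsq = np.array([np.corrcoef(X[:, j], scores)[0, 1] ** 2 for j in range(5)])
        assert rsq.sum() == pytest.approx(lam, abs=1e-8)

    def test_unstandardized_input_rejected(self, rng):
        with pytest.raises(ValueError, match="standardized"):
            cluster_homogeneity(rng.standard_normal((30, 3)) * 5 + 2)


class TestDissimilarity:
    def test_exact_copy_gives_zero(self, rng):
        x = std_matrix(rng.standard_normal((40, 1))).values
        assert dissimilarity(x, x.copy()) == pytest.approx(0.0, abs=1e-10)

    def test_uncorrelated_pair_gives_one(self, rng):
        # construct exactly orthogonal standardized columns
        x = rng.standard_normal(40)
        y = rng.standard_normal(40)
        y = y - np.polyval(np.polyfit(x, y, 1), x)
        m = std_matrix(np.column_stack([x, y]))
        d = dissimilarity(m.values[:, :1], m.values[:, 1:])
        assert d == pytest.approx(1.0, abs=1e-10)

    def test_correlated_pair_gives_one_minus_r(self, rng):
        X = std_matrix(rng.standard_normal((50, 2))).values
        r = abs(float(np.corrcoef(X.T)[0, 1]))
        d = dissimilarity(X[:, :1], X[:, 1:])
        assert d == pytest.approx(1 - r, abs=1e-10)

    def test_overlapping_blocks_rejected(self, rng):
        X = std_matrix(rng.standard_normal((30, 2))).values
        with pytest.raises(ValueError, match="disjoint"):
            dissimilarity(X, X, a_ix=(0, 1), b_ix=(1, 2))


class TestAgglomerate:
    def test_duplicate_pairs_merge_first_at_height_zero(self, two_duplicate_pairs):
        tree = agglomerate(two_duplicate_pairs)
        first_two = tree.merges[:2]
        assert all(abs(h) < 1e-9 for _, _, h, _ in first_two)
        merged_sets = {frozenset(tree.members[m[3]]) for m in first_two}
        assert merged_sets == {frozenset({0, 1}), frozenset({2, 3})}

    def test_merge_count_and_nonnegative_heights(self, rng):
        m = std_matrix(rng.standard_normal((40, 7)))
        tree = agglomerate(m)
        assert len(tree.merges) == 6
        assert (tree.heights >= -1e-12).all()

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        r = np.random.default_rng(seed)
        p = int(r.integers(3, 7))
        W = r.standard_normal((p, 2))
        X = r.standard_normal((30, 2)) @ W.T + r.standard_normal((30, p))
        m = std_matrix(X)
        tree = agglomerate(m)
        oracle = brute_force_agglomeration(m.values)
        for (a, b, h, _), (oa, ob, od) in zip(tree.merges, oracle):
            assert {frozenset(tree.members[a]), frozenset(tree.members[b])} == {oa, ob}
            assert h == pytest.approx(od, abs=1e-9)

    def test_single_variable_rejected(self, rng):
        m = std_matrix(rng.standard_normal((30, 1)))
        with pytest.raises(ValueError, match="at least 2"):
            agglomerate(m)

    def test_total_homogeneity_drops_by_merge_height(self, rng):
        m = std_matrix(rng.standard_normal((50, 6)))
        tree = agglomerate(m)
        p = m.n_variables
        total = float(p)
        for step, (_, _, h, _) in enumerate(tree.merges, start=1):
            part = cut_tree(tree, p - step, m)
            total -= h
            assert part.total_homogeneity == pytest.approx(total, abs=1e-8)


class TestCutTree:
    def test_all_singletons_total_homogeneity_p(self, rng):
        m = std_matrix(rng.standard_normal((30, 5)))
        part = cut_tree(agglomerate(m), 5, m)
        assert part.total_homogeneity == pytest.approx(5.0)
        assert all(lam == pytest.approx(1.0) for lam in part.homogeneity)

    def test_single_block_equals_full_lambda1(self, rng):
        m = std_matrix(rng.standard_normal((30, 5)))
        part = cut_tree(agglomerate(m), 1, m)
        corr = np.corrcoef(m.values.T)
        assert part.homogeneity[0] == pytest.approx(np.linalg.eigvalsh(corr)[-1], abs=1e-10)

    def test_duplicate_pairs_recovered_at_k2(self, two_duplicate_pairs):
        part = cut_tree(agglomerate(two_duplicate_pairs), 2, two_duplicate_pairs)
        assert part.blocks == [["x1", "x2"], ["y1", "y2"]]

    def test_out_of_range_k(self, two_duplicate_pairs):
        tree = agglomerate(two_duplicate_pairs)
        with pytest.raises(ValueError):
            tree.clusters_at(0)
        with pytest.raises(ValueError):
            tree.clusters_at(5)


class TestSuggestBlockCount:
    @pytest.mark.parametrize("seed", range(5))
    def test_three_strong_blocks_detected(self, seed):
        cfg = SyntheticConfig(n=200, block_sizes=[[10, 10, 10]], betas=[[0, 0, 0]],
                              a=0.9, censoring=0.0, seed=seed)
        layers, _, _ = generate_multiomics(cfg)
        m = standardize(layers[0])
        sug = suggest_block_count(agglomerate(m), 10)
        assert sug.k == 3
        assert not sug.low_confidence

    def test_independent_variables_flagged_flat(self, rng):
        m = std_matrix(rng.standard_normal((200, 25)))
        sug = suggest_block_count(agglomerate(m), 10)
        assert sug.low_confidence
        assert sug.k >= 2

    def test_two_duplicate_pairs_suggest_two(self, two_duplicate_pairs):
        sug = suggest_block_count(agglomerate(two_duplicate_pairs), 4)
        assert sug.k == 2


class TestEigenPaths:
    def test_power_iteration_agrees_with_dense(self, rng):
        X = rng.standard_normal((100, 60))
        corr = np.corrcoef(X.T)
        dense = float(np.linalg.eigvalsh(corr)[-1])
        assert _power_lambda1(corr) == pytest.approx(dense, abs=1e-6)

    def test_lambda1_singleton(self):
        assert _lambda1(np.array([[1.0]])) == 1.0


class TestEstimator:
    def test_labels_match_partition(self, two_duplicate_pairs):
        est = VariableClustering(n_clusters=2).fit(two_duplicate_pairs.data)
        assert est.n_clusters_ == 2
        assert est.labels_.tolist() == [0, 0, 1, 1]

    def test_transform_returns_block_scores(self, two_duplicate_pairs):
        est = VariableClustering(n_clusters=2).fit(two_duplicate_pairs.data)
        scores = est.transform(two_duplicate_pairs.data)
        assert scores.shape == (40, 2)
        # synthetic variable of a duplicate pair is (up to sign/scale) the variable
        r = np.corrcoef(scores[1], two_duplicate_pairs.values[:, 0])[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-8)

    def test_get_set_params_roundtrip(self):
        est = VariableClustering(n_clusters=4, k_max=8)
        assert VariableClustering(**est.get_params()).get_params() == est.get_params()
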