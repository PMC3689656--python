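"""Mutual information, discretization, and MaxRel/mRMR ranking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm
from sklearn.metrics import mutual_info_score

from pyruvoylsite.mrmr import (
    MRMRSelector,
    discretize,
    maxrel_rank,
    mrmr_rank,
    mutual_information,
)


def brute_force_mi(x, y):
    """Independent oracle: explicit double loop over the joint histogram."""
    x, y = np.asarray(x), np.asarray(y)
    n = len(x)
    total = 0.0
    for xv in np.unique(x):
        for yv in np.unique(y):
            pxy = np.sum((x == xv) & (y == yv)) / n
            if pxy == 0:
                continue
            px = np.sum(x == xv) / n
            py = np.sum(y == yv) / n
            total += pxy * np.log2(pxy / (px * py))
    return total


def entropy_bits(x):
    _, counts = np.unique(x, return_counts=True)
    p = counts / counts.sum()
    return -np.sum(p * np.log2(p))


class TestMutualInformation:
    def test_identical_balanced_binary_is_one_bit(self):
        x = np.array([0, 1] * 10)
        assert mutual_information(x, x) == pytest.approx(1.0)

    def test_factorial_independence_is_zero(self):
        # full factorial balance: joint = product of marginals exactly
        x = np.repeat([0, 1, 2], 4)
        y = np.tile([0, 1], 6)
        assert mutual_information(x, y) == pytest.approx(0.0, abs=1e-15)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 3, 40)
        y = rng.integers(0, 2, 40)
        assert mutual_information(x, y) == pytest.approx(
            brute_force_mi(x, y), abs=1e-12
        )

    def test_matches_sklearn_up_to_base(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 4, 200)
        y = (x + rng.integers(0, 2, 200)) % 4
        assert mutual_information(x, y) == pytest.approx(
            mutual_info_score(x, y) / np.log(2), abs=1e-12
        )

    def test_self_information_is_entropy(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 5, 100)
        assert mutual_information(x, x) == pytest.approx(entropy_bits(x), abs=1e-12)

    @settings(max_examples=60, deadline=None)
    @given(
        data=st.lists(
            st.tuples(st.integers(0, 3), st.integers(0, 3)), min_size=2, max_size=60
        )
    )
    def test_symmetric_nonnegative_relabel_invariant(self, data):
        x = np.array([a for a, _ in data])
        y = np.array([b for _, b in data])
        mi = mutual_information(x, y)
        assert mi >= -1e-15
        assert mi == pytest.approx(mutual_information(y, x), abs=1e-12)
        # relabeling codes does not change MI
        assert mi == pytest.approx(mutual_information(7 - x, y * 10 + 3), abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mutual_information([0, 1], [0, 1, 0])


class TestDiscretize:
    def test_binary_feature_passthrough(self):
        X = np.array([[0.0], [1.0], [1.0], [0.0]])
        disc = discretize(X)
        assert disc.n_levels[0] == 2
        assert set(disc.codes[:, 0]) == {0, 1}

    def test_constant_feature_single_code_zero_mi(self):
        X = np.column_stack([np.full(50, 3.3), np.arange(50.0)])
        disc = discretize(X)
        assert disc.n_levels[0] == 1
        y = np.arange(50) % 2
        assert mutual_information(disc.codes[:, 0], y) == 0.0

    def test_normal_sample_three_bin_proportions(self):
        """mean +/- sigma binning puts ~16/68/16% in the three bins."""
        rng = np.random.default_rng(0)
        n = 10000
        X = rng.standard_normal((n, 1))
        disc = discretize(X)
        props = np.bincount(disc.codes[:, 0], minlength=3) / n
        tail = norm.cdf(-1)
        for observed, expected in zip(props, [tail, 1 - 2 * tail, tail]):
            se = np.sqrt(expected * (1 - expected) / n)
            assert abs(observed - expected) < 3 * se


def oracle_mrmr(codes, y, mutual_information=mutual_information):
    """Exhaustive per-round argmax oracle, recomputed from scratch each round."""
    p = codes.shape[1]
    D = [mutual_information(codes[:, j], y) for j in range(p)]
    selected = []
    remaining = list(range(p))
    for _ in range(p):
        best, best_score = None, -np.inf
        for j in remaining:
            R = (
                np.mean([mutual_information(codes[:, j], codes[:, s]) for s in selected])
                if selected
                else 0.0
            )
            score = D[j] - R
            if score > best_score + 1e-12:
                best, best_score = j, score
        selected.append(best)
        remaining.remove(best)
    return selected


class TestRanking:
    def test_label_copy_ranks_first(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 60)
        X = rng.random((60, 5))
        X[:, 3] = y
        disc = discretize(X)
        assert maxrel_rank(disc, y)[0] == 3
        assert mrmr_rank(disc, y).mrmr[0] == 3

    def test_constant_features_keep_catalog_order(self):
        X = np.ones((20, 4))
        y = np.arange(20) % 2
        disc = discretize(X)
        assert list(maxrel_rank(disc, y)) == [0, 1, 2, 3]

    def test_maxrel_agrees_with_independent_sort(self):
        rng = np.random.default_rng(4)
        X = rng.integers(0, 3, (80, 7)).astype(float)
        y = rng.integers(0, 2, 80)
        disc = discretize(X)
        D = np.array([mutual_information(disc.codes[:, j], y) for j in range(7)])
        expected = np.argsort(-D, kind="stable")
        np.testing.assert_array_equal(maxrel_rank(disc, y), expected)

    def test_duplicate_of_top_feature_deferred(self):
        """A redundant copy of the best feature ranks after an independent one."""
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 200)
        strong = np.where(rng.random(200) < 0.9, y, 1 - y).astype(float)
        weak = np.where(rng.random(200) < 0.75, y, 1 - y).astype(float)
        X = np.column_stack([strong, strong.copy(), weak])
        ranking = mrmr_rank(discretize(X), y).mrmr
        assert ranking[0] == 0  # the strong feature
        assert ranking[1] == 2  # the weak-but-new one beats the duplicate
        assert ranking[2] == 1

    def test_single_class_labels_rejected(self):
        X = np.random.default_rng(0).random((10, 3))
        with pytest.raises(ValueError, match="single class"):
            mrmr_rank(discretize(X), np.zeros(10))

    @pytest.mark.parametrize("seed", range(8))
    def test_greedy_trace_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 61))
        p = int(rng.integers(3, 9))
        X = rng.integers(0, 3, (n, p)).astype(float)
        y = rng.integers(0, 2, n)
        disc = discretize(X)
        assert list(mrmr_rank(disc, y).mrmr) == oracle_mrmr(disc.codes, y)

    def test_rankings_are_permutations_with_increasing_rounds(self):
        rng = np.random.default_rng(9)
        X = rng.random((50, 12))
        y = rng.integers(0, 2, 50)
        ranking = mrmr_rank(discretize(X), y)
        assert sorted(ranking.maxrel) == list(range(12))
        assert sorted(ranking.mrmr) == list(range(12))
        rounds = [ranking.round_of(j) for j in ranking.mrmr]
        assert rounds == list(range(1, 13))

    def test_truncated_rounds_still_permutation(self):
        rng = np.random.default_rng(9)
        X = rng.random((40, 10))
        y = rng.integers(0, 2, 40)
        full = mrmr_rank(discretize(X), y)
        part = mrmr_rank(discretize(X), y, n_rounds=4)
        assert list(part.mrmr[:4]) == list(full.mrmr[:4])
        assert sorted(part.mrmr) == list(range(10))


class TestSelector:
    def test_sklearn_contract_and_support(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 80)
        X = rng.random((80, 6))
        X[:, 2] = y + 0.01 * rng.random(80)
        sel = MRMRSelector(n_features=2).fit(X, y)
        assert sel.get_support().sum() == 2
        assert sel.get_support()[2]
        assert sel.transform(X).shape == (80, 2)
        params = sel.get_params()
        assert params["n_features"] == 2
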