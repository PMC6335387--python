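"""Ponocny's T10 / T11 statistics and their bootstrap p-values."""

import numpy as np
import pytest
from scipy.stats import kstest

from raschfit.datagen import (
    GeneratingModelSpec,
    ResponseMatrix,
    items_for_spec,
    simulate_matrix,
)
from raschfit.exceptions import DegenerateDataError
from raschfit.lr_test import ScoreGroupSplit, median_split
from raschfit.nonparam import nonparam_test, t10_statistic, t11_statistic


def brute_force_t10(data, groups):
    """Direct tabulation of sum_{i<j} |Nij(h)Nji(l) - Nij(l)Nji(h)|."""
    n = data.shape[1]
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            nij_h = int(np.sum((data[groups == 1, i] == 1) & (data[groups == 1, j] == 0)))
            nji_h = int(np.sum((data[groups == 1, j] == 1) & (data[groups == 1, i] == 0)))
            nij_l = int(np.sum((data[groups == 0, i] == 1) & (data[groups == 0, j] == 0)))
            nji_l = int(np.sum((data[groups == 0, j] == 1) & (data[groups == 0, i] == 0)))
            total += abs(nij_h * nji_l - nij_l * nji_h)
    return total


class TestT10:
    def test_hand_constructed_pair_counts(self):
        # seven persons built to give N12(h)=3, N21(h)=1, N12(l)=1, N21(l)=2;
        # a third item pushes the first four persons to the high score group
        data = np.array([
            [1, 0, 1],
            [1, 0, 1],
            [1, 0, 1],
            [0, 1, 1],
            [1, 0, 0],
            [0, 1, 0],
            [0, 1, 0],
        ])
        X = ResponseMatrix(data)
        split = median_split(X)
        assert list(split.group_of_person) == [1, 1, 1, 1, 0, 0, 0]
        # pair (1,2) alone contributes |3*2 - 1*1| = 5
        pair_only = t10_statistic(ResponseMatrix(data[:, :2]), split)
        assert pair_only == 5
        assert t10_statistic(X, split) == brute_force_t10(data, split.group_of_person)

    def test_identical_groups_give_zero(self):
        half = np.array([[1, 0, 1], [0, 1, 0], [1, 1, 0], [0, 0, 1]])
        data = np.vstack([half, half])
        split = ScoreGroupSplit(
            group_of_person=np.r_[np.zeros(4, int), np.ones(4, int)], G=2,
            rule="copies")
        assert t10_statistic(ResponseMatrix(data), split) == 0

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            data = (rng.random((30, 3)) < rng.uniform(0.3, 0.7)).astype(int)
            X = ResponseMatrix(data)
            try:
                split = median_split(X)
            except Exception:
                continue
            assert t10_statistic(X, split) == brute_force_t10(data, split.group_of_person)


class TestT11:
    def test_self_comparison_is_zero(self, small_matrix):
        rho = np.corrcoef(small_matrix.data, rowvar=False)
        assert t11_statistic(small_matrix, rho) == 0

    def test_two_item_hand_value(self):
        # observed phi 0.5 against null mean phi 0.1 leaves |0.5 - 0.1|
        data = np.array([[1, 1], [1, 1], [1, 0], [0, 1], [0, 0], [0, 0]])
        X = ResponseMatrix(data)
        r = np.corrcoef(data, rowvar=False)[0, 1]
        rho = np.array([[1.0, r - 0.4], [r - 0.4, 1.0]])
        assert np.isclose(t11_statistic(X, rho), 0.4)

    def test_row_permutation_invariance(self, small_matrix):
        rho = np.full((3, 3), 0.1)
        perm = np.random.default_rng(0).permutation(small_matrix.n_persons)
        a = t11_statistic(small_matrix, rho)
        b = t11_statistic(ResponseMatrix(small_matrix.data[perm]), rho)
        assert np.isclose(a, b)

    def test_constant_column_rejected(self):
        data = np.array([[1, 1], [1, 0], [1, 1]])
        with pytest.raises(DegenerateDataError):
            t11_statistic(ResponseMatrix(data), np.eye(2))


class TestBootstrapPValues:
    def test_p_value_in_unit_interval_and_reproducible(self):
        rng = np.random.default_rng(20)
        spec = GeneratingModelSpec("rasch")
        items = items_for_spec(spec, 8, rng)
        X = simulate_matrix(spec, 80, items, rng)
        res1 = nonparam_test(X, "T11", B=100, rng=np.random.default_rng(5))
        res2 = nonparam_test(X, "T11", B=100, rng=np.random.default_rng(5))
        assert 0 < res1.p_value <= 1
        assert res1.p_value == res2.p_value
        assert res1.df is None

    def test_singleton_reference_set_yields_p_one(self):
        # staircase pattern: margins admit exactly one matrix
        X = ResponseMatrix(np.array([[1, 0, 0], [1, 1, 0]]))
        res = nonparam_test(X, "T10", B=20, rng=np.random.default_rng(0))
        assert res.p_value == 1.0
        assert res.diagnostics["singleton"]

    def test_unknown_statistic_rejected(self, small_matrix):
        with pytest.raises(ValueError):
            nonparam_test(small_matrix, "T99", B=10)

    @pytest.mark.parametrize("which", ["T10", "T11"])
    def test_null_p_values_approximately_uniform(self, which):
        # Rasch-null p-value distribution passes a KS uniformity check
        spec = GeneratingModelSpec("rasch")
        ss = np.random.SeedSequence(55)
        item_ss, *rep_ss = ss.spawn(301)
        items = items_for_spec(spec, 10, np.random.default_rng(item_ss))
        ps = []
        for r in range(300):
            rng = np.random.default_rng(rep_ss[r])
            X = simulate_matrix(spec, 100, items, rng)
            ps.append(nonparam_test(X, which, B=200, rng=rng).p_value)
        assert kstest(np.asarray(ps), "uniform").pvalue > 0.01
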