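"""The SSIR rule engine: exact p-values, node scoring, rule enumeration
and threshold selection."""

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom

from ssirchrom import (ClassSplit, enumerate_rules, evaluate_node,
                       rule_pvalue, select_variables)
from ssirchrom.binarize import BinaryCode
from ssirchrom.ssir import Rule, _pvalue_fraction

from conftest import CORK_K, CORK_N, CORK_VARIABLES


def bruteforce_pvalue(N, K, n, k):
    """Independent oracle: enumerate every size-n subset of N samples (the
    first K are in-class) and count those holding >= k in-class members."""
    hits = total = 0
    for subset in itertools.combinations(range(N), n):
        total += 1
        if sum(1 for s in subset if s < K) >= k:
            hits += 1
    return Fraction(hits, total)


class TestRulePvalue:
    @pytest.mark.parametrize("var,row", sorted(CORK_VARIABLES.items()))
    def test_published_study_pvalues_to_two_sf(self, var, row):
        """All 13 variable p-values of the 56-cork study reproduce to 2
        significant figures from the printed level counts."""
        n, k, _, expected = row
        assert rule_pvalue(CORK_N, CORK_K, n, k) == pytest.approx(
            expected, rel=0.05
        )

    def test_tiny_case_exact_by_enumeration(self):
        # drawing 2 of 6 samples, 3 in-class, both in-class: 3/15 subsets
        assert rule_pvalue(6, 3, 2, 2) == pytest.approx(0.2, abs=1e-15)
        assert bruteforce_pvalue(6, 3, 2, 2) == Fraction(3, 15)

    def test_empty_selection_has_p_one(self):
        assert rule_pvalue(56, 28, 0, 0) == 1.0
        assert rule_pvalue(7, 3, 0, 0) == 1.0

    @pytest.mark.parametrize(
        "args",
        [(10, 4, 5, 5), (10, 4, 11, 2), (10, 11, 2, 1), (10, 4, 3, -1)],
    )
    def test_invalid_arguments_rejected(self, args):
        with pytest.raises(ValueError):
            rule_pvalue(*args)

    def test_exhaustive_agreement_with_bruteforce_small_n(self):
        """For every (N<=9, K, n, k), the closed form equals subset
        enumeration exactly, in rational arithmetic."""
        for N in range(2, 10):
            for K in range(1, N):
                for n in range(0, N + 1):
                    counts = {}
                    for subset in itertools.combinations(range(N), n):
                        j = sum(1 for s in subset if s < K)
                        counts[j] = counts.get(j, 0) + 1
                    total = comb(N, n)
                    for k in range(0, min(n, K) + 1):
                        tail = sum(c for j, c in counts.items() if j >= k)
                        assert _pvalue_fraction(N, K, n, k) == Fraction(
                            tail, total
                        ), (N, K, n, k)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_scipy_hypergeometric_tail(self, data):
        """Independent cross-check against scipy's survival function."""
        N = data.draw(st.integers(2, 60))
        K = data.draw(st.integers(1, N - 1))
        n = data.draw(st.integers(0, N))
        k = data.draw(st.integers(0, min(n, K)))
        assert rule_pvalue(N, K, n, k) == pytest.approx(
            float(hypergeom.sf(k - 1, N, K, n)), rel=1e-9
        )

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.data())
    def test_complement_symmetry_exact(self, data):
        """Selecting n of N enriched for the K-class is exactly as
        surprising as the complementary selection enriched for the other
        class."""
        N = data.draw(st.integers(2, 40))
        K = data.draw(st.integers(1, N - 1))
        n = data.draw(st.integers(0, N))
        k = data.draw(st.integers(max(0, n - (N - K)), min(n, K)))
        comp = _pvalue_fraction(N, N - K, N - n, (N - K) - (n - k))
        assert _pvalue_fraction(N, K, n, k) == comp

    def test_strictly_decreasing_in_k(self):
        for N, K, n in [(56, 28, 29), (20, 10, 8), (12, 5, 7)]:
            ps = [rule_pvalue(N, K, n, k)
                  for k in range(max(0, n - (N - K)), min(n, K) + 1)]
            assert all(a > b for a, b in zip(ps, ps[1:]))


def make_code(levels, node_indices=None):
    levels = np.asarray(levels, dtype=np.uint8)
    if node_indices is None:
        node_indices = np.arange(levels.shape[1])
    return BinaryCode([f"s{i}" for i in range(levels.shape[0])],
                      np.asarray(node_indices), levels, 0.01)


def column_split(high_class1, high_class0, n1, n0):
    """Build a one-node code with the given per-class high counts."""
    col = [1] * high_class1 + [0] * (n1 - high_class1) \
        + [1] * high_class0 + [0] * (n0 - high_class0)
    labels = [1] * n1 + [0] * n0
    return make_code(np.array(col)[:, None]), ClassSplit.from_array(labels)


class TestEvaluateNode:
    def test_study_variable_one_counts(self):
        """High in 27 of 28 treated and 2 of 28 non-treated: the treated
        direction sees 27 of 29 selected."""
        code, split = column_split(27, 2, 28, 28)
        treated, _ = evaluate_node(code, 0, split)
        assert (treated.selected_n, treated.selected_in_class) == (29, 27)
        assert treated.direction == 1
        assert treated.p_value == pytest.approx(1.4e-12, rel=0.05)

    def test_study_variable_twelve_non_treated_direction(self):
        """High in 10 non-treated and 0 treated: the non-treated direction
        rule selects 10 of 10."""
        code, split = column_split(0, 10, 28, 28)
        _, non_treated = evaluate_node(code, 0, split)
        assert (non_treated.selected_n, non_treated.selected_in_class) == (10, 10)
        assert non_treated.direction == 0
        assert non_treated.p_value == pytest.approx(3.7e-4, rel=0.05)

    def test_perfect_classifier_bound(self):
        code, split = column_split(6, 0, 6, 6)
        treated, _ = evaluate_node(code, 0, split)
        assert treated.p_value == pytest.approx(1 / comb(12, 6), abs=1e-15)

    def test_per_class_level_counts_are_complementary(self):
        """High count plus low count per class equals the class size."""
        rng = np.random.default_rng(31)
        labels = np.array([1] * 9 + [0] * 7)
        code = make_code(rng.integers(0, 2, (16, 5)))
        split = ClassSplit.from_array(labels)
        for j in range(5):
            col = code.levels[:, j]
            for cls, size in ((1, 9), (0, 7)):
                high = int(((col == 1) & (labels == cls)).sum())
                low = int(((col == 0) & (labels == cls)).sum())
                assert high + low == size

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_direction_rules_use_best_level_symmetrically(self, seed):
        """The treated-direction p from the high level equals the
        non-treated-direction p from the low level, and evaluate_node
        retains the minimum per direction."""
        rng = np.random.default_rng(seed)
        n1, n0 = rng.integers(2, 10), rng.integers(2, 10)
        col = rng.integers(0, 2, n1 + n0)
        code = make_code(col[:, None])
        split = ClassSplit.from_array([1] * n1 + [0] * n0)
        treated, non_treated = evaluate_node(code, 0, split)
        candidates = {}
        for direction, K in ((1, n1), (0, n0)):
            ps = []
            labels = np.array([1] * n1 + [0] * n0)
            for level in (0, 1):
                sel = col == level
                k = int((sel & (labels == direction)).sum())
                ps.append(rule_pvalue(n1 + n0, K, int(sel.sum()), k))
            candidates[direction] = min(ps)
        assert treated.p_value == pytest.approx(candidates[1], rel=1e-9)
        assert non_treated.p_value == pytest.approx(candidates[0], rel=1e-9)


class TestEnumerateRules:
    def test_order_one_counts_both_levels_per_node(self):
        code = make_code(np.array([[1, 0, 1], [0, 1, 1], [1, 1, 0], [0, 0, 0]]))
        split = ClassSplit.from_array([1, 1, 0, 0])
        rules = list(enumerate_rules(code, split, max_order=1))
        assert len(rules) == 6  # 3 nodes x 2 levels
        assert all(r.order == 1 for r in rules)

    def test_order_two_conjunction_count(self):
        """3 representatives at order 2 add C(3,2) x 4 = 12 conjunctions."""
        code = make_code(np.array([[1, 0, 1], [0, 1, 1], [1, 1, 0], [1, 0, 0]]))
        split = ClassSplit.from_array([1, 1, 0, 0])
        rules = list(enumerate_rules(code, split, max_order=2))
        order2 = [r for r in rules if r.order == 2]
        # conjunctions whose conditions nobody matches are skipped
        possible = 0
        for (a, b) in itertools.combinations(range(3), 2):
            for la, lb in itertools.product((0, 1), repeat=2):
                if ((code.levels[:, a] == la).any()
                        and (code.levels[:, b] == lb).any()):
                    possible += 1
        assert len(order2) == possible <= 12

    def test_conjunction_selection_counts(self):
        """Only the sample matching both stated levels is selected."""
        levels = np.array([[1, 1], [1, 0], [0, 1], [0, 0]])
        code = make_code(levels)
        split = ClassSplit.from_array([1, 0, 1, 0])
        rules = list(enumerate_rules(code, split, max_order=2))
        both_high = [r for r in rules
                     if r.conditions == ((0, 1), (1, 1))]
        assert len(both_high) == 1
        assert both_high[0].selected_n == 1

    def test_order_three_agrees_with_direct_counting(self):
        rng = np.random.default_rng(37)
        levels = rng.integers(0, 2, (8, 4)).astype(np.uint8)
        code = make_code(levels)
        labels = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        split = ClassSplit.from_array(labels)
        for rule in enumerate_rules(code, split, max_order=3):
            mask = np.ones(8, dtype=bool)
            for node, level in rule.conditions:
                mask &= levels[:, node] == level
            assert rule.selected_n == int(mask.sum())
            k = int((mask & (labels == rule.direction)).sum())
            assert rule.selected_in_class == k

    def test_invalid_order_rejected(self):
        code = make_code(np.array([[1], [0]]))
        split = ClassSplit.from_array([1, 0])
        with pytest.raises(ValueError):
            list(enumerate_rules(code, split, max_order=4))

    def test_stream_order_deterministic(self):
        rng = np.random.default_rng(41)
        code = make_code(rng.integers(0, 2, (6, 5)))
        split = ClassSplit.from_array([1, 1, 1, 0, 0, 0])
        first = [r.conditions for r in enumerate_rules(code, split, 2)]
        second = [r.conditions for r in enumerate_rules(code, split, 2)]
        assert first == second


class TestSelectVariables:
    def cork_rules(self):
        return [
            Rule(((var, 1),), n, k, d, rule_pvalue(
                CORK_N, CORK_K if d == 1 else CORK_N - CORK_K, n, k))
            for var, (n, k, d, _) in sorted(CORK_VARIABLES.items())
        ]

    def test_study_threshold_keeps_all_13(self):
        result = select_variables(self.cork_rules(), threshold=0.0005)
        assert result.n_expanded == 13
        assert max(v.p_value for v in result.expanded) <= 5e-4

    def test_tighter_threshold_keeps_8_of_13(self):
        result = select_variables(self.cork_rules(), threshold=1e-4)
        assert result.n_expanded == 8

    def test_empty_rule_set(self):
        result = select_variables([], threshold=0.0005)
        assert result.n_expanded == 0
        assert result.representatives == {}

    def test_degeneracy_expansion_and_vote_counts(self):
        rules = [
            Rule(((3, 1),), 4, 4, 1, 1e-5),
            Rule(((3, 0),), 4, 4, 0, 2e-5),
            Rule(((7, 1),), 5, 2, 1, 0.3),
        ]
        result = select_variables(rules, 1e-4, degeneracy_map={3: [3, 9], 7: [7]})
        assert result.expanded_node_indices == [3, 9]
        assert result.votes == {3: 2}
        # expanded members inherit the representative's best rule
        assert all(v.p_value == 1e-5 and v.direction == 1
                   for v in result.expanded)

    def test_ranking_ascending_p_then_node_index(self):
        rules = [
            Rule(((5, 1),), 4, 4, 1, 1e-3),
            Rule(((2, 1),), 4, 4, 1, 1e-3),
            Rule(((9, 1),), 6, 6, 1, 1e-6),
        ]
        result = select_variables(rules, 1e-2)
        assert result.expanded_node_indices == [9, 2, 5]

    def test_to_frame_carries_grid_coordinates(self, paper_grid):
        node = paper_grid.node_index_of(3, 92)  # [7.0, 7.333) x 95.0
        rules = [Rule(((node, 1),), 4, 4, 1, 1e-5)]
        frame = select_variables(rules, 1e-4).to_frame(paper_grid)
        assert frame.loc[0, "mass_center"] == 95.0
        assert frame.loc[0, "time_start_min"] == pytest.approx(7.0)


class TestNullCalibration:
    def test_label_permutation_false_positive_rate(self):
        """Under label shuffles of a class-neutral binary dataset, the
        fraction of node tests reaching p <= alpha stays within the
        binomial bound of alpha."""
        rng = np.random.default_rng(43)
        n_samples, n_nodes, reps, alpha = 20, 50, 1000, 0.05
        levels = rng.integers(0, 2, (n_samples, n_nodes))
        labels = np.array([1] * 10 + [0] * 10)
        hits = total = 0
        for _ in range(reps):
            perm = rng.permutation(labels)
            split = ClassSplit.from_array(perm)
            code = make_code(levels)
            for treated, non_treated in (
                evaluate_node(code, j, split) for j in range(n_nodes)
            ):
                total += 1
                # one two-sided test per node
                hits += min(treated.p_value, non_treated.p_value) <= alpha / 2
        rate = hits / total
        # discrete p-values make the test conservative; allow 3 binomial SDs
        bound = alpha + 3 * np.sqrt(alpha * (1 - alpha) / total)
        assert rate <= bound
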