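"""SSIR rule engine: exact enrichment p-values, rule enumeration, selection.

Superposing Significant Interaction Rules treats every conjunction of
(node, level) conditions as an *a priori random extractor*: the rule selects
the samples matching all its conditions, and under the null the class
composition of that selection is hypergeometric.  The upper-tail probability
of observing at least the attained number of in-class samples is the rule's
p-value; nodes appearing in at least one rule at or below the significance
threshold are selected, and each node's count of significant rules (its
*votes*) superposes the evidence across rules.

p-values are computed with exact integer combinatorics (no floating-point
tail summation), so thresholding decisions are reproducible to the last bit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache
from math import comb
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .binarize import BinaryCode

__all__ = [
    "ClassSplit",
    "Rule",
    "SelectionResult",
    "rule_pvalue",
    "evaluate_node",
    "enumerate_rules",
    "select_variables",
]

LEVEL_NAMES = {0: "low", 1: "high"}


@dataclass(frozen=True)
class ClassSplit:
    """Binary class membership of the samples (1 = treated class)."""

    labels: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(l not in (0, 1) for l in self.labels):
            raise ValueError("labels must be 0 or 1")
        if not 0 < self.K < self.N:
            raise ValueError("both classes must be non-empty")

    @classmethod
    def from_array(cls, labels) -> "ClassSplit":
        return cls(tuple(int(l) for l in np.asarray(labels)))

    @property
    def N(self) -> int:
        return len(self.labels)

    @property
    def K(self) -> int:
        return sum(self.labels)

    def class_size(self, direction: int) -> int:
        return self.K if direction == 1 else self.N - self.K

    def mask(self, direction: int = 1) -> np.ndarray:
        arr = np.asarray(self.labels, dtype=np.uint8)
        return arr == direction


@dataclass(frozen=True)
class Rule:
    """A conjunction of (node_index, level) conditions with its enrichment.

    ``selected_n`` samples match every condition; ``selected_in_class`` of
    them belong to the enriched class ``direction`` (1 = treated,
    0 = non-treated).  ``p_value`` is the exact hypergeometric upper tail
    for that composition.
    """

    conditions: tuple[tuple[int, int], ...]
    selected_n: int
    selected_in_class: int
    direction: int
    p_value: float

    @property
    def order(self) -> int:
        return len(self.conditions)

    @property
    def nodes(self) -> tuple[int, ...]:
        return tuple(n for n, _ in self.conditions)

    def describe(self) -> str:
        conds = " & ".join(
            f"node{n}={LEVEL_NAMES[lv]}" for n, lv in self.conditions
        )
        cls = "treated" if self.direction == 1 else "non-treated"
        return (f"{conds} -> {self.selected_in_class}/{self.selected_n} "
                f"{cls}, p={self.p_value:.3g}")


@lru_cache(maxsize=200_000)
def _pvalue_fraction(N: int, K: int, n_selected: int, k_in_class: int) -> Fraction:
    num = sum(
        comb(K, j) * comb(N - K, n_selected - j)
        for j in range(k_in_class, min(n_selected, K) + 1)
    )
    return Fraction(num, comb(N, n_selected))


def rule_pvalue(N: int, K: int, n_selected: int, k_in_class: int) -> float:
    """Exact probability of drawing >= ``k_in_class`` class members.

    A rule that selects ``n_selected`` of ``N`` samples uniformly at random
    would contain X ~ Hypergeometric(N, K, n_selected) members of the
    K-sample class; the p-value is P(X >= k_in_class), computed with exact
    integer combinatorics and returned as a float in (0, 1].
    """
    if not (0 <= K <= N):
        raise ValueError(f"need 0 <= K <= N, got K={K}, N={N}")
    if not (0 <= n_selected <= N):
        raise ValueError(f"need 0 <= n_selected <= N, got {n_selected}")
    if not (0 <= k_in_class <= min(n_selected, K)):
        raise ValueError(
            f"need 0 <= k_in_class <= min(n_selected, K); got "
            f"k={k_in_class}, n={n_selected}, K={K}"
        )
    return float(_pvalue_fraction(N, K, n_selected, k_in_class))


def _directional_rule(
    conditions: tuple[tuple[int, int], ...],
    n_sel: int,
    k_class1: int,
    split: ClassSplit,
    direction: int,
) -> Rule:
    k = k_class1 if direction == 1 else n_sel - k_class1
    p = rule_pvalue(split.N, split.class_size(direction), n_sel, k)
    return Rule(conditions, n_sel, k, direction, p)


def evaluate_node(
    code: BinaryCode, node_index: int, split: ClassSplit
) -> tuple[Rule, Rule]:
    """Score one node in both class directions.

    For each direction the better (lower-p) of the two levels is retained:
    by the hypergeometric complement symmetry, "high enriches class 1" and
    "low enriches class 0" carry the same p-value, so each direction has a
    well-defined best level.  Returns (treated-direction rule,
    non-treated-direction rule).
    """
    col = code.column(node_index)
    rules = {}
    for direction in (1, 0):
        candidates = []
        for level in (1, 0):
            sel = col == level
            n_sel = int(sel.sum())
            k1 = int((sel & split.mask(1)).sum())
            candidates.append(
                _directional_rule(((int(node_index), level),), n_sel, k1,
                                  split, direction)
            )
        rules[direction] = min(candidates, key=lambda r: r.p_value)
    return rules[1], rules[0]


def _packed_columns(code: BinaryCode) -> dict[tuple[int, int], int]:
    """Bit-pack each (column position, level) selection over samples."""
    packed = {}
    for j in range(code.n_nodes):
        col = code.levels[:, j]
        bits_high = 0
        for i, v in enumerate(col):
            if v:
                bits_high |= 1 << i
        full = (1 << code.n_samples) - 1
        packed[(j, 1)] = bits_high
        packed[(j, 0)] = full ^ bits_high
    return packed


def enumerate_rules(
    code: BinaryCode, split: ClassSplit, max_order: int = 1
) -> Iterator[Rule]:
    """Stream all conjunction rules of order 1..max_order, best direction each.

    Order r evaluates every combination of r distinct nodes with every one
    of the 2^r level assignments, in lexicographic order of column position
    then level tuple.  Each conjunction is scored for both class directions
    and yielded once with the lower-p direction (ties resolved toward the
    treated class).  Conjunctions containing a condition no sample matches
    are skipped — they cannot select anything, hence cannot be enriched.
    """
    if max_order not in (1, 2, 3):
        raise ValueError("max_order must be 1, 2 or 3")
    if len(code.sample_ids) != split.N:
        raise ValueError("code and split disagree on sample count")
    node_of = code.node_indices

    # order 1: yield both level assignments per node
    for j in range(code.n_nodes):
        col = code.levels[:, j]
        for level in (0, 1):
            sel = col == level
            n_sel = int(sel.sum())
            k1 = int((sel & split.mask(1)).sum())
            conds = ((int(node_of[j]), level),)
            r1 = _directional_rule(conds, n_sel, k1, split, 1)
            r0 = _directional_rule(conds, n_sel, k1, split, 0)
            yield r1 if r1.p_value <= r0.p_value else r0

    if max_order == 1:
        return

    packed = _packed_columns(code)
    class1_bits = 0
    for i, l in enumerate(split.labels):
        if l == 1:
            class1_bits |= 1 << i
    for order in range(2, max_order + 1):
        for combo in itertools.combinations(range(code.n_nodes), order):
            for levels in itertools.product((0, 1), repeat=order):
                masks = [packed[(j, lv)] for j, lv in zip(combo, levels)]
                if any(m == 0 for m in masks):
                    continue
                inter = masks[0]
                for m in masks[1:]:
                    inter &= m
                n_sel = inter.bit_count()
                k1 = (inter & class1_bits).bit_count()
                conds = tuple(
                    (int(node_of[j]), lv) for j, lv in zip(combo, levels)
                )
                r1 = _directional_rule(conds, n_sel, k1, split, 1)
                r0 = _directional_rule(conds, n_sel, k1, split, 0)
                yield r1 if r1.p_value <= r0.p_value else r0


@dataclass
class SelectedVariable:
    """One node in the final expanded variable table."""

    node_index: int
    representative: int
    direction: int
    p_value: float
    votes: int


@dataclass
class SelectionResult:
    """Outcome of thresholding the rule stream.

    ``representatives`` maps each selected representative node to its best
    (lowest-p) significant rule; ``votes`` counts significant rules per
    node; ``expanded`` lists every variable after degeneracy expansion,
    sorted by ascending p-value then node index.
    """

    threshold: float
    representatives: dict[int, Rule]
    votes: dict[int, int]
    expanded: list[SelectedVariable]

    @property
    def n_representatives(self) -> int:
        return len(self.representatives)

    @property
    def n_expanded(self) -> int:
        return len(self.expanded)

    @property
    def expanded_node_indices(self) -> list[int]:
        return [v.node_index for v in self.expanded]

    def to_frame(self, grid=None) -> pd.DataFrame:
        """Tabulate expanded variables; adds grid coordinates when given."""
        rows = []
        for rank, var in enumerate(self.expanded, start=1):
            row = {
                "variable": rank,
                "node_index": var.node_index,
                "representative": var.representative,
                "direction": "treated" if var.direction == 1 else "non_treated",
                "p_value": var.p_value,
                "votes": var.votes,
            }
            if grid is not None:
                t0, t1 = grid.node_time_interval(var.node_index)
                row["time_start_min"] = t0
                row["time_end_min"] = t1
                row["mass_center"] = float(grid.node_mass_center(var.node_index))
            rows.append(row)
        return pd.DataFrame(rows)


def select_variables(
    rules: Iterable[Rule],
    threshold: float = 0.0005,
    degeneracy_map: dict[int, list[int]] | None = None,
) -> SelectionResult:
    """Retain nodes appearing in at least one rule with p <= threshold.

    No multiple-testing correction is applied; the raw threshold is the
    selection criterion.  Representatives are expanded through the
    degeneracy map so every node whose binary pattern equals a selected
    representative's is reported, inheriting the representative's direction
    and p-value.
    """
    # Ties between a high-level rule and its complement-symmetric low-level
    # twin are broken toward the high level, so a variable's reported
    # direction is the class its *high* state enriches.
    def rank(rule: Rule):
        return (rule.p_value, rule.order,
                tuple(1 - lv for _, lv in rule.conditions))

    best: dict[int, Rule] = {}
    votes: dict[int, int] = {}
    for rule in rules:
        if rule.p_value > threshold:
            continue
        for node in rule.nodes:
            votes[node] = votes.get(node, 0) + 1
            cur = best.get(node)
            if cur is None or rank(rule) < rank(cur):
                best[node] = rule
    expanded = []
    for rep, rule in best.items():
        members = degeneracy_map.get(rep, [rep]) if degeneracy_map else [rep]
        for member in members:
            expanded.append(
                SelectedVariable(member, rep, rule.direction, rule.p_value,
                                 votes[rep])
            )
    expanded.sort(key=lambda v: (v.p_value, v.node_index))
    return SelectionResult(threshold, best, votes, expanded)
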