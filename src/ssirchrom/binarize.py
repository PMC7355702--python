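"""Binary codification of node intensities and degeneracy reduction.

Each sample's node sums are dichotomized into low/high levels: the top
fraction (default 1%) of that sample's node values become *high*, the rest
*low*.  Columns that never change across samples carry no class information
and are removed; columns with bit-identical patterns are collapsed under a
single representative so the rule engine never scores the same pattern
twice.  The degeneracy map is kept so selected representatives can be
expanded back to every node they stand for.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import NodeMatrix

__all__ = ["BinaryCode", "dichotomize", "drop_constant", "group_degenerate"]


@dataclass
class BinaryCode:
    """Samples x nodes binary level matrix with provenance.

    ``levels`` columns correspond to ``node_indices`` (original grid node
    indices).  After :func:`group_degenerate`, ``degeneracy_map`` maps each
    representative node index to the sorted list of all node indices (itself
    included) whose pre-grouping columns were bit-identical to it.
    """

    sample_ids: list[str]
    node_indices: np.ndarray
    levels: np.ndarray  # (n_samples, n_nodes) of uint8, 0=low 1=high
    top_fraction: float
    degeneracy_map: dict[int, list[int]] | None = None
    n_constant_dropped: int | None = None
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.node_indices = np.asarray(self.node_indices, dtype=int)
        self.levels = np.asarray(self.levels, dtype=np.uint8)
        if self.levels.shape != (len(self.sample_ids), self.node_indices.size):
            raise ValueError("levels shape does not match sample_ids x nodes")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_nodes(self) -> int:
        return self.node_indices.size

    def column(self, node_index: int) -> np.ndarray:
        pos = np.nonzero(self.node_indices == node_index)[0]
        if pos.size == 0:
            raise KeyError(f"node {node_index} not present in this code")
        return self.levels[:, pos[0]]

    def expand(self) -> "BinaryCode":
        """Reconstruct the pre-grouping code from the degeneracy map.

        Lossless inverse of :func:`group_degenerate`: every represented node
        gets back a column identical to its representative's.
        """
        if self.degeneracy_map is None:
            return self
        cols: dict[int, np.ndarray] = {}
        for j, rep in enumerate(self.node_indices):
            for member in self.degeneracy_map[int(rep)]:
                cols[member] = self.levels[:, j]
        order = np.array(sorted(cols), dtype=int)
        levels = np.column_stack([cols[i] for i in order]) if order.size else \
            np.zeros((self.n_samples, 0), dtype=np.uint8)
        return BinaryCode(
            self.sample_ids, order, levels, self.top_fraction,
            degeneracy_map=None, n_constant_dropped=self.n_constant_dropped,
            labels=self.labels,
        )

    def to_csv(self, path, degeneracy_path=None, grid=None) -> None:
        label = (lambda i: grid.node_label(i)) if grid is not None else str
        df = pd.DataFrame(
            self.levels,
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=[label(int(i)) for i in self.node_indices],
        )
        df.to_csv(path)
        if degeneracy_path is not None and self.degeneracy_map is not None:
            rows = [
                (label(rep), label(member))
                for rep, members in sorted(self.degeneracy_map.items())
                for member in members
            ]
            pd.DataFrame(rows, columns=["representative", "member"]).to_csv(
                degeneracy_path, index=False
            )


def dichotomize(
    matrix: NodeMatrix, top_fraction: float = 0.01, scope: str = "per_sample"
) -> BinaryCode:
    """Binarize node sums: the top fraction of values become level high.

    The cut is a rank rule, not an interpolated quantile: with n values,
    exactly ``ceil(top_fraction * n)`` are high.  Ties at the cutoff are
    broken deterministically in favor of the lower node index.  With
    ``scope='per_sample'`` (default) each sample is ranked on its own;
    ``scope='pooled'`` ranks all samples' values together.
    """
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must lie in (0, 1)")
    if scope not in ("per_sample", "pooled"):
        raise ValueError(f"unknown percentile scope {scope!r}")
    values = matrix.values
    n_samples, n_nodes = values.shape
    levels = np.zeros((n_samples, n_nodes), dtype=np.uint8)
    if scope == "per_sample":
        k = math.ceil(top_fraction * n_nodes)
        for i in range(n_samples):
            # stable argsort on -v keeps ascending node order among ties,
            # so the lower-indexed node wins the last high slot
            order = np.argsort(-values[i], kind="stable")
            levels[i, order[:k]] = 1
    else:
        k = math.ceil(top_fraction * values.size)
        flat_order = np.argsort(-values.ravel(), kind="stable")
        levels.ravel()[flat_order[:k]] = 1
    return BinaryCode(
        list(matrix.sample_ids),
        np.arange(n_nodes),
        levels,
        top_fraction,
        labels=None if matrix.labels is None else matrix.labels.copy(),
    )


def drop_constant(code: BinaryCode) -> BinaryCode:
    """Remove columns that are all-low or all-high across samples."""
    if code.n_samples < 2:
        raise ValueError("constant-node filtering needs at least 2 samples")
    col_sum = code.levels.sum(axis=0)
    keep = (col_sum > 0) & (col_sum < code.n_samples)
    dropped = int((~keep).sum())
    if not keep.any():
        warnings.warn("all node columns are constant; nothing survives",
                      stacklevel=2)
    return BinaryCode(
        code.sample_ids,
        code.node_indices[keep],
        code.levels[:, keep],
        code.top_fraction,
        degeneracy_map=None,
        n_constant_dropped=dropped,
        labels=code.labels,
    )


def group_degenerate(code: BinaryCode) -> BinaryCode:
    """Collapse bit-identical columns under their lowest-index member.

    Returns a code whose columns are the representatives only, plus a
    ``degeneracy_map`` from each representative to all members of its group
    (singleton groups for non-degenerate nodes), sufficient to reconstruct
    the input exactly via :meth:`BinaryCode.expand`.
    """
    if code.n_nodes == 0:
        return BinaryCode(code.sample_ids, code.node_indices, code.levels,
                          code.top_fraction, degeneracy_map={},
                          n_constant_dropped=code.n_constant_dropped,
                          labels=code.labels)
    _, first_pos, inverse = np.unique(
        code.levels, axis=1, return_index=True, return_inverse=True
    )
    # np.unique's first occurrence is the lowest column position, and columns
    # are stored in ascending node_index order, so the representative is the
    # lowest node index of its group.
    degeneracy: dict[int, list[int]] = {}
    for group_id, rep_pos in enumerate(first_pos):
        members = code.node_indices[inverse == group_id]
        degeneracy[int(code.node_indices[rep_pos])] = [int(m) for m in np.sort(members)]
    rep_positions = np.sort(first_pos)
    return BinaryCode(
        code.sample_ids,
        code.node_indices[rep_positions],
        code.levels[:, rep_positions],
        code.top_fraction,
        degeneracy_map=degeneracy,
        n_constant_dropped=code.n_constant_dropped,
        labels=code.labels,
    )
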