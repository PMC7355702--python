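"""Time x mass grid: binning of scan registers into a samples x nodes matrix.

The chromatographic plane is tiled by a rectangular grid.  Retention time is
cut into half-open intervals [t0, t1) of fixed width; m/z is cut into
half-open windows [c - r, c + r) around an arithmetic sequence of centers.
A *node* is one (time interval, mass window) cell.  Each sample's registers
are mean-normalized inside the grid coverage window and summed into nodes,
giving the non-negative samples x nodes :class:`NodeMatrix` that every later
stage (binarization, rule selection, PCA) consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_chromatograms import SampleRun

__all__ = ["GridSpec", "Node", "NodeMatrix", "build_grid",
           "normalize_sample", "accumulate", "build_node_matrix"]


@dataclass(frozen=True)
class GridSpec:
    """Rectangular time x mass grid definition.

    Mass windows have radius ``mass_radius`` (default half the step, so the
    windows tile the mass axis without gaps); both time and mass bins are
    half-open on the right.
    """

    time_start: float
    time_end: float
    time_step: float
    mass_center_min: float
    mass_center_max: float
    mass_step: float
    mass_radius: float | None = None

    def __post_init__(self) -> None:
        if self.time_step <= 0 or self.mass_step <= 0:
            raise ValueError("time_step and mass_step must be positive")
        if self.time_end <= self.time_start:
            raise ValueError("time_end must exceed time_start")
        if self.mass_center_max < self.mass_center_min:
            raise ValueError("mass_center_max must be >= mass_center_min")
        if self.mass_radius is None:
            object.__setattr__(self, "mass_radius", self.mass_step / 2.0)
        if not 0 < self.mass_radius <= self.mass_step / 2.0 + 1e-12:
            raise ValueError("mass_radius must lie in (0, mass_step/2]")
        if self.n_time < 1:
            raise ValueError("grid must contain at least one time interval")

    @property
    def n_time(self) -> int:
        return int(round((self.time_end - self.time_start) / self.time_step))

    @property
    def n_mass(self) -> int:
        return int(round(
            (self.mass_center_max - self.mass_center_min) / self.mass_step
        )) + 1

    @property
    def n_nodes(self) -> int:
        return self.n_time * self.n_mass

    @property
    def mass_centers(self) -> np.ndarray:
        return self.mass_center_min + self.mass_step * np.arange(self.n_mass)

    @property
    def time_edges(self) -> np.ndarray:
        return self.time_start + self.time_step * np.arange(self.n_time + 1)

    # node_index = time_index * n_mass + mass_index
    def node_time_index(self, node_index) -> np.ndarray:
        return np.asarray(node_index) // self.n_mass

    def node_mass_index(self, node_index) -> np.ndarray:
        return np.asarray(node_index) % self.n_mass

    def node_mass_center(self, node_index) -> np.ndarray:
        return self.mass_center_min + self.mass_step * self.node_mass_index(node_index)

    def node_time_interval(self, node_index: int) -> tuple[float, float]:
        ti = int(self.node_time_index(node_index))
        return (self.time_start + ti * self.time_step,
                self.time_start + (ti + 1) * self.time_step)

    def node(self, node_index: int) -> "Node":
        return Node(self.node_time_interval(node_index),
                    float(self.node_mass_center(node_index)), int(node_index))

    def node_label(self, node_index: int) -> str:
        t0, t1 = self.node_time_interval(node_index)
        m = self.node_mass_center(node_index)
        return f"t[{t0:.3f},{t1:.3f})_m{m:g}"

    def node_index_of(self, time_index: int, mass_index: int) -> int:
        if not (0 <= time_index < self.n_time and 0 <= mass_index < self.n_mass):
            raise IndexError("time or mass index outside the grid")
        return time_index * self.n_mass + mass_index

    def bin_registers(self, times, mz):
        """Map registers to node indices.

        Returns (node_index, in_window) arrays; node_index is only valid
        where in_window is True.  Time bins are [t0, t1); mass windows are
        [c - r, c + r), evaluated exactly so edge registers land
        deterministically.
        """
        times = np.asarray(times, dtype=float)
        mz = np.asarray(mz, dtype=float)
        t_idx = np.floor((times - self.time_start) / self.time_step).astype(int)
        # Guard against float drift at the right edge of a bin: a time equal
        # to an edge must open the next bin.
        edge = self.time_start + (t_idx + 1) * self.time_step
        t_idx[times >= edge] += 1
        lower = self.time_start + t_idx * self.time_step
        t_idx[times < lower] -= 1
        t_ok = (t_idx >= 0) & (t_idx < self.n_time) & (times >= self.time_start)

        m_idx = np.floor(
            (mz - (self.mass_center_min - self.mass_radius)) / self.mass_step
        ).astype(int)
        centers_lo = self.mass_center_min + m_idx * self.mass_step - self.mass_radius
        m_idx[mz >= centers_lo + self.mass_step] += 1
        m_idx[mz < centers_lo] -= 1
        center = self.mass_center_min + m_idx * self.mass_step
        m_ok = (
            (m_idx >= 0)
            & (m_idx < self.n_mass)
            & (mz >= center - self.mass_radius)
            & (mz < center + self.mass_radius)
        )
        ok = t_ok & m_ok
        idx = np.where(ok, t_idx * self.n_mass + np.clip(m_idx, 0, self.n_mass - 1), 0)
        return idx, ok

    def node_labels(self) -> list[str]:
        return [self.node_label(i) for i in range(self.n_nodes)]


@dataclass(frozen=True)
class Node:
    """One grid cell: a half-open time interval and a mass-window center."""

    time_interval: tuple[float, float]
    mass_center: float
    node_index: int


def build_grid(
    time_start: float,
    time_end: float,
    time_step: float,
    mass_center_min: float,
    mass_center_max: float,
    mass_step: float,
    mass_radius: float | None = None,
) -> GridSpec:
    """Construct a :class:`GridSpec`; see that class for conventions."""
    return GridSpec(time_start, time_end, time_step,
                    mass_center_min, mass_center_max, mass_step, mass_radius)


def normalize_sample(
    run: SampleRun, grid: GridSpec, target_mean: float = 1000.0
) -> tuple[SampleRun, float]:
    """Rescale a run so its mean in-window intensity equals ``target_mean``.

    The mean is computed over the registers inside the grid coverage window
    only — the same registers that will be accumulated — so signal outside
    the analysis window (internal standards, late eluters) cannot leak into
    the scale.  Returns the rescaled run and the multiplicative factor
    applied.
    """
    _, ok = grid.bin_registers(run.times, run.mz)
    if not ok.any():
        raise ValueError(
            f"sample {run.sample_id!r} has no registers inside the grid window"
        )
    mean = run.intensity[ok].mean()
    if mean == 0:
        raise ValueError(
            f"sample {run.sample_id!r}: all in-window intensities are zero; "
            "normalization scale is undefined"
        )
    factor = target_mean / mean
    return run.scaled(factor), float(factor)


def accumulate(run: SampleRun, grid: GridSpec) -> tuple[np.ndarray, int]:
    """Sum a (normalized) run's registers into grid nodes.

    Every in-window register is added to exactly one node; out-of-window
    registers are dropped and counted.  Returns (node sums of length
    ``grid.n_nodes``, dropped-register count).
    """
    idx, ok = grid.bin_registers(run.times, run.mz)
    row = np.bincount(idx[ok], weights=run.intensity[ok], minlength=grid.n_nodes)
    return row, int((~ok).sum())


@dataclass
class NodeMatrix:
    """Samples x nodes matrix of accumulated normalized intensities."""

    grid: GridSpec
    sample_ids: list[str]
    values: np.ndarray  # (n_samples, n_nodes), >= 0
    norm_factors: np.ndarray
    dropped_counts: np.ndarray
    labels: np.ndarray | None = None  # per-sample 0/1 or None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), self.grid.n_nodes):
            raise ValueError("values shape does not match sample_ids x grid")
        if np.any(self.values < 0):
            raise ValueError("node sums must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_csv(self, path, sidecar_path=None) -> None:
        df = pd.DataFrame(self.values, index=pd.Index(self.sample_ids, name="sample_id"),
                          columns=self.grid.node_labels())
        df.to_csv(path, float_format="%.10g")
        if sidecar_path is not None:
            side = pd.DataFrame(
                {
                    "sample_id": self.sample_ids,
                    "norm_factor": self.norm_factors,
                    "dropped_registers": self.dropped_counts,
                }
            )
            if self.labels is not None:
                side["label"] = self.labels
            side.to_csv(sidecar_path, index=False, float_format="%.10g")


def build_node_matrix(
    runs: Sequence[SampleRun], grid: GridSpec, target_mean: float = 1000.0
) -> NodeMatrix:
    """Normalize and accumulate each run; order follows the input sequence."""
    ids = [r.sample_id for r in runs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id in dataset")
    rows, factors, dropped = [], [], []
    for run in runs:
        scaled, f = normalize_sample(run, grid, target_mean)
        row, d = accumulate(scaled, grid)
        rows.append(row)
        factors.append(f)
        dropped.append(d)
    labels = [r.label for r in runs]
    return NodeMatrix(
        grid,
        ids,
        np.vstack(rows),
        np.asarray(factors),
        np.asarray(dropped, dtype=int),
        labels=None if any(l is None for l in labels) else np.asarray(labels, dtype=int),
    )
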