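"""Two-class synthetic GC-MS scan generator with a ground-truth manifest.

Each dataset contains a shared set of class-independent background
compounds plus marker compounds whose abundance differs between the two
classes (treatment generates or removes them).  Compounds elute as Gaussian
peaks in time, sampled on a regular scan grid; fragment spectra are sparse
sticks at integer m/z (unit-resolution ion-trap behavior), so half-integer
mass windows of the analysis grid stay empty.  Per-compound-per-sample
multiplicative lognormal noise models run-to-run abundance variation, an
additive exponential baseline register is drawn per scan, and a per-sample
global scale factor emulates injection/extraction efficiency differences
(which the pipeline's mean normalization must absorb).

The manifest returned alongside the samples lists every analysis-grid node
(time bin x fragment mass) expected to discriminate the classes, with its
direction, so selection output can be scored against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .grid import GridSpec, build_grid
from .io_chromatograms import SampleRun, write_labels, write_long_table, write_mzml

__all__ = ["MarkerSpec", "SimConfig", "cork_markers", "default_grid",
           "generate", "write_dataset", "manifest_node_indices"]

# Relative fragment abundance above which a marker ion is expected to
# produce a clearly discriminating node (weaker fragments may drown in
# baseline and are not promised by the manifest).
MANIFEST_ABUNDANCE_MIN = 0.2


@dataclass(frozen=True)
class MarkerSpec:
    """A class-dependent marker compound.

    ``amplitude`` is the apex intensity of the base ion in class 0
    (non-treated); class 1 (treated) gets ``amplitude * class_effect``.
    ``class_effect`` > 1 means the compound is generated by the treatment,
    < 1 removed by it, 0 absent from treated samples; ``math.inf`` is the
    limiting "absent from non-treated" case, where class 0 gets zero and
    class 1 gets ``amplitude``.
    """

    name: str
    retention_time: float  # minutes
    rt_sigma: float  # minutes, Gaussian elution width
    fragments: dict[int, float]  # integer amu -> relative abundance (max 1)
    amplitude: float
    class_effect: float

    def __post_init__(self) -> None:
        if self.rt_sigma <= 0:
            raise ValueError("rt_sigma must be positive")
        if not self.fragments:
            raise ValueError("marker needs at least one fragment")
        if any(a <= 0 for a in self.fragments.values()):
            raise ValueError("fragment abundances must be positive")
        if abs(max(self.fragments.values()) - 1.0) > 1e-9:
            raise ValueError("fragment abundances must be normalized to max 1")
        if self.class_effect < 0:
            raise ValueError("class_effect must be >= 0 (or math.inf)")

    def class_amplitudes(self) -> tuple[float, float]:
        """(class-0 apex, class-1 apex) of the base ion."""
        if math.isinf(self.class_effect):
            return 0.0, self.amplitude
        return self.amplitude, self.amplitude * self.class_effect

    @property
    def direction(self) -> int | None:
        """Class in which the marker is enriched (None if class-neutral)."""
        a0, a1 = self.class_amplitudes()
        if a1 > a0:
            return 1
        if a0 > a1:
            return 0
        return None


def cork_markers() -> list[MarkerSpec]:
    """Three markers emulating the cork washing-treatment chemistry.

    Two furanic compounds generated by the thermal treatment — a
    furfural-like marker (fragments 51/67/95/96/97, ~7.2 min) and a
    5-methylfurfural-like marker (fragments 53/109/110, ~10.5 min) — plus
    one unidentified compound (fragments 51/78, ~9.2 min) removed by the
    washing cycles.  Retention times sit at time-bin centers of the default
    analysis grid so each peak concentrates in a single node column.
    """
    return [
        MarkerSpec(
            "furfural_like", 7.1667, 0.04,
            {96: 1.0, 95: 0.95, 67: 0.30, 51: 0.25, 97: 0.20},
            amplitude=250.0, class_effect=20.0,
        ),
        MarkerSpec(
            "methylfurfural_like", 10.5, 0.04,
            {110: 1.0, 109: 0.90, 53: 0.30},
            amplitude=250.0, class_effect=20.0,
        ),
        MarkerSpec(
            "removed_compound", 9.1667, 0.04,
            {78: 1.0, 51: 0.50},
            amplitude=5000.0, class_effect=0.05,
        ),
    ]


def default_grid() -> GridSpec:
    """The default analysis grid used to define manifest nodes."""
    return build_grid(6.0, 17.0, 1.0 / 3.0, 49.0, 170.0, 0.5)


@dataclass(frozen=True)
class SimConfig:
    """Synthetic dataset parameters; ``seed`` is mandatory."""

    seed: int
    n_per_class: int = 10
    markers: tuple[MarkerSpec, ...] = field(
        default_factory=lambda: tuple(cork_markers())
    )
    n_background_compounds: int = 30
    time_start: float = 6.0
    time_end: float = 17.0
    scan_interval: float = 0.005  # minutes between scans
    background_rt_sigma: float = 0.04
    mz_jitter_sd: float = 0.05  # amu; clipped so sticks stay within +-0.24
    intensity_noise_cv: float = 0.2  # lognormal CV per compound per sample
    baseline_scale: float = 20.0  # exponential baseline intensity per scan
    global_scale_range: tuple[float, float] = (0.5, 2.0)
    intensity_floor: float = 0.5  # registers below this are not emitted

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.scan_interval <= 0 or self.time_end <= self.time_start:
            raise ValueError("invalid scan window")
        lo, hi = self.global_scale_range
        if not 0 < lo <= hi:
            raise ValueError("global_scale_range must be positive and ordered")


@dataclass(frozen=True)
class _Compound:
    rt: float
    sigma: float
    ions: np.ndarray
    abundances: np.ndarray
    amp0: float
    amp1: float


def _draw_background(config: SimConfig, rng: np.random.Generator) -> list[_Compound]:
    compounds = []
    margin = 0.3
    for _ in range(config.n_background_compounds):
        rt = rng.uniform(config.time_start + margin, config.time_end - margin)
        n_ions = int(rng.integers(3, 7))
        ions = rng.choice(np.arange(49, 171), size=n_ions, replace=False)
        ab = rng.uniform(0.2, 1.0, size=n_ions)
        ab /= ab.max()
        amp = float(np.exp(rng.normal(np.log(1000.0), 0.8)))
        compounds.append(
            _Compound(float(rt), config.background_rt_sigma,
                      np.sort(ions), ab[np.argsort(ions)], amp, amp)
        )
    return compounds


def _marker_compound(m: MarkerSpec, config: SimConfig) -> _Compound:
    if not (config.time_start + 4 * m.rt_sigma
            <= m.retention_time
            <= config.time_end - 4 * m.rt_sigma):
        raise ValueError(
            f"marker {m.name!r} at {m.retention_time} min falls outside the "
            f"scan window [{config.time_start}, {config.time_end}] min"
        )
    ions = np.array(sorted(m.fragments), dtype=int)
    ab = np.array([m.fragments[i] for i in ions], dtype=float)
    amp0, amp1 = m.class_amplitudes()
    return _Compound(m.retention_time, m.rt_sigma, ions, ab, amp0, amp1)


def _emit_compound(
    comp: _Compound, label: int, scale: float, config: SimConfig,
    rng: np.random.Generator,
):
    """One compound's registers for one sample; rng consumption is fixed
    regardless of amplitudes so datasets differing only in class effects
    stay draw-aligned."""
    s = math.sqrt(math.log(1.0 + config.intensity_noise_cv**2))
    noise = math.exp(rng.normal(-s * s / 2.0, s)) if s > 0 else 1.0
    i0 = max(0, math.ceil((comp.rt - 4 * comp.sigma - config.time_start)
                          / config.scan_interval))
    i1 = math.floor((comp.rt + 4 * comp.sigma - config.time_start)
                    / config.scan_interval)
    times = config.time_start + config.scan_interval * np.arange(i0, i1 + 1)
    gauss = np.exp(-((times - comp.rt) ** 2) / (2 * comp.sigma**2))
    amp = (comp.amp1 if label == 1 else comp.amp0) * noise * scale
    inten = amp * np.outer(gauss, comp.abundances)  # (scans, ions)
    jitter = np.clip(
        rng.normal(0.0, config.mz_jitter_sd, size=inten.shape), -0.24, 0.24
    )
    mz = comp.ions[None, :] + jitter
    t = np.broadcast_to(times[:, None], inten.shape)
    keep = inten >= config.intensity_floor
    return t[keep], mz[keep], inten[keep]


def generate(config: SimConfig) -> tuple[list[SampleRun], pd.DataFrame]:
    """Generate labeled runs and the discriminating-node manifest.

    Samples are ordered non-treated (class 0) first, then treated
    (class 1); ids encode the class.  The manifest covers each marker
    fragment with relative abundance >= ``MANIFEST_ABUNDANCE_MIN``, located
    on the default analysis grid.
    """
    rng = np.random.default_rng(config.seed)
    background = _draw_background(config, rng)
    markers = [_marker_compound(m, config) for m in config.markers]
    compounds = background + markers

    n_scans = int(round((config.time_end - config.time_start)
                        / config.scan_interval))
    scan_times = config.time_start + config.scan_interval * np.arange(n_scans)

    runs = []
    labels = [0] * config.n_per_class + [1] * config.n_per_class
    for i, label in enumerate(labels):
        sid = f"sim{i:02d}_c{label}"
        scale = float(rng.uniform(*config.global_scale_range))
        parts_t, parts_m, parts_i = [], [], []
        for comp in compounds:
            t, m, v = _emit_compound(comp, label, scale, config, rng)
            parts_t.append(t)
            parts_m.append(m)
            parts_i.append(v)
        # additive baseline: one register per scan at a random integer mass
        base_mz = rng.integers(49, 171, size=n_scans) + np.clip(
            rng.normal(0.0, config.mz_jitter_sd, size=n_scans), -0.24, 0.24
        )
        base_int = rng.exponential(config.baseline_scale, size=n_scans) * scale
        parts_t.append(scan_times)
        parts_m.append(base_mz)
        parts_i.append(base_int)
        times = np.concatenate(parts_t)
        mzs = np.concatenate(parts_m)
        intens = np.concatenate(parts_i)
        order = np.argsort(times, kind="stable")
        runs.append(SampleRun(sid, times[order], mzs[order], intens[order],
                              label=label))
    return runs, build_manifest(config)


def build_manifest(config: SimConfig, grid: GridSpec | None = None) -> pd.DataFrame:
    """Nodes of the analysis grid expected to discriminate the classes."""
    grid = grid or default_grid()
    rows = []
    for m in config.markers:
        if m.direction is None:
            continue
        t_idx, ok = grid.bin_registers([m.retention_time], [grid.mass_center_min])
        time_index = int(grid.node_time_index(t_idx[0]))
        for ion, ab in sorted(m.fragments.items()):
            if ab < MANIFEST_ABUNDANCE_MIN:
                continue
            mass_index = int(round((ion - grid.mass_center_min) / grid.mass_step))
            node = grid.node_index_of(time_index, mass_index)
            t0, t1 = grid.node_time_interval(node)
            rows.append(
                {
                    "marker": m.name,
                    "node_index": node,
                    "time_start_min": t0,
                    "time_end_min": t1,
                    "mass_center": float(ion),
                    "direction": m.direction,
                }
            )
    return pd.DataFrame(rows)


def manifest_node_indices(manifest: pd.DataFrame) -> set[int]:
    return set(int(i) for i in manifest["node_index"])


def write_dataset(
    runs: Sequence[SampleRun],
    manifest: pd.DataFrame,
    outdir,
    fmt: str = "long_table",
) -> list[Path]:
    """Write one file per sample plus labels and manifest side files."""
    if fmt not in ("long_table", "mzml"):
        raise ValueError(f"unknown format {fmt!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for run in runs:
        if fmt == "mzml":
            p = outdir / f"{run.sample_id}.mzML"
            write_mzml(run, p)
        else:
            p = outdir / f"{run.sample_id}.csv"
            write_long_table([run], p)
        paths.append(p)
    labels_path = outdir / "labels.csv"
    write_labels(runs, labels_path)
    manifest_path = outdir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return paths + [labels_path, manifest_path]
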