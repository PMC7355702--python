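"""End-to-end pipeline orchestration and leave-one-out cross-validation.

The pipeline runs grid -> normalize -> accumulate -> dichotomize -> constant
filter -> degeneracy grouping -> SSIR selection -> PCA -> discriminant, in
that order, deterministically.  Leave-one-out validation re-derives the
*entire* pipeline from the raw scan registers for every held-out sample:
the percentile cuts, surviving nodes, degeneracy map, p-values, PCA and
discriminant are all functions of the remaining samples only, so no
information from the held-out sample can leak into its own prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .binarize import BinaryCode, dichotomize, drop_constant, group_degenerate
from .grid import GridSpec, NodeMatrix, accumulate, build_grid, \
    build_node_matrix, normalize_sample
from .io_chromatograms import SampleRun
from .modeling import DiscriminantModel, MetricsReport, PCAModel, \
    discriminant_fit, discriminant_predict, evaluate, pca_fit, pca_transform
from .ssir import ClassSplit, SelectionResult, enumerate_rules, select_variables

__all__ = ["PipelineConfig", "PipelineResult", "CVReport",
           "NoSignificantVariables", "run_pipeline", "loo_validate"]


class NoSignificantVariables(RuntimeError):
    """Raised when no node reaches the significance threshold."""


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters with their default analysis values.

    Defaults correspond to an 11-minute window in 20-second partitions and
    unit-resolution masses from 49 to 170 amu in 0.5-amu windows (radius
    0.25), per-sample mean normalization to 1000 counts, a top-1% high
    level, order-1 rules at a raw significance threshold of 5e-4,
    autoscaled PCA and a one-component discriminant.
    """

    time_start: float = 6.0
    time_end: float = 17.0
    time_step: float = 1.0 / 3.0
    mass_center_min: float = 49.0
    mass_center_max: float = 170.0
    mass_step: float = 0.5
    mass_radius: float | None = None
    target_mean: float = 1000.0
    top_fraction: float = 0.01
    percentile_scope: str = "per_sample"
    max_order: int = 1
    p_threshold: float = 0.0005
    scaling_mode: str = "autoscale"
    n_components: int = 1

    def grid(self) -> GridSpec:
        return build_grid(
            self.time_start, self.time_end, self.time_step,
            self.mass_center_min, self.mass_center_max, self.mass_step,
            self.mass_radius,
        )

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a flat key/value mapping")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


@dataclass
class PipelineResult:
    config: PipelineConfig
    matrix: NodeMatrix
    code: BinaryCode  # representatives, after filtering and grouping
    selection: SelectionResult
    pca: PCAModel
    discriminant: DiscriminantModel
    metrics: MetricsReport
    scores: np.ndarray
    predictions: np.ndarray

    def descriptor_matrix(self) -> np.ndarray:
        return self.matrix.values[:, self.selection.expanded_node_indices]


def _check_dataset(runs: Sequence[SampleRun], min_per_class: int) -> np.ndarray:
    labels = np.array([r.label for r in runs])
    if any(l is None for l in labels):
        raise ValueError("every sample needs a 0/1 class label")
    labels = labels.astype(int)
    for cls in (0, 1):
        if (labels == cls).sum() < min_per_class:
            raise ValueError(
                f"need at least {min_per_class} samples of class {cls}"
            )
    return labels


def _select_from_code(code: BinaryCode, labels: np.ndarray,
                      config: PipelineConfig) -> SelectionResult:
    split = ClassSplit.from_array(labels)
    rules = enumerate_rules(code, split, max_order=config.max_order)
    return select_variables(rules, config.p_threshold, code.degeneracy_map)


def run_pipeline(
    runs: Sequence[SampleRun], config: PipelineConfig | None = None
) -> PipelineResult:
    """Fit the full selection + classification pipeline on labeled runs.

    Raises :class:`NoSignificantVariables` if no node reaches the
    significance threshold.
    """
    config = config or PipelineConfig()
    labels = _check_dataset(runs, min_per_class=2)
    grid = config.grid()
    matrix = build_node_matrix(runs, grid, config.target_mean)
    code = dichotomize(matrix, config.top_fraction, config.percentile_scope)
    code = group_degenerate(drop_constant(code))
    selection = _select_from_code(code, labels, config)
    if selection.n_expanded == 0:
        raise NoSignificantVariables(
            f"no significant variables at threshold {config.p_threshold}"
        )
    X = matrix.values[:, selection.expanded_node_indices]
    pca = pca_fit(X, config.scaling_mode,
                  variable_ids=selection.expanded_node_indices)
    scores = pca_transform(pca, X)
    k = min(config.n_components, pca.n_components)
    da = discriminant_fit(scores, labels, k)
    predictions = discriminant_predict(da, scores)
    metrics = evaluate(predictions, labels)
    return PipelineResult(config, matrix, code, selection, pca, da, metrics,
                          scores, predictions)


@dataclass
class CVReport:
    """Leave-one-out results, one row per (fold, component count)."""

    folds: pd.DataFrame  # sample_id, k, n_selected, predicted, true

    @property
    def n_folds(self) -> int:
        return self.folds["sample_id"].nunique()

    def metrics(self, k: int) -> MetricsReport:
        sub = self.folds[(self.folds["k"] == k) & (self.folds["predicted"] >= 0)]
        return evaluate(sub["predicted"].to_numpy(), sub["true"].to_numpy())

    def accuracy(self, k: int) -> float:
        sub = self.folds[self.folds["k"] == k]
        return float((sub["predicted"] == sub["true"]).mean())

    def no_model_folds(self) -> list[str]:
        sub = self.folds[self.folds["predicted"] < 0]
        return sorted(sub["sample_id"].unique())

    def to_csv(self, path) -> None:
        self.folds.to_csv(path, index=False)


def _predict_heldout(
    run: SampleRun,
    grid: GridSpec,
    config: PipelineConfig,
    selection: SelectionResult,
    pca: PCAModel,
    discriminants: dict[int, DiscriminantModel],
) -> dict[int, int]:
    """Grid, normalize and classify one held-out sample with a fitted fold."""
    scaled, _ = normalize_sample(run, grid, config.target_mean)
    row, _ = accumulate(scaled, grid)
    x = row[selection.expanded_node_indices]
    score = pca_transform(pca, x[None, :])
    return {
        k: int(discriminant_predict(da, score)[0])
        for k, da in discriminants.items()
    }


def loo_validate(
    runs: Sequence[SampleRun],
    config: PipelineConfig | None = None,
    k_range: Sequence[int] = (1, 2, 3, 4, 5),
) -> CVReport:
    """Full-pipeline leave-one-out cross-validation.

    For every sample the pipeline is refit from the raw registers of the
    remaining samples; the held-out sample is then normalized with its own
    mean, accumulated on the fold's grid, reduced to the fold's selected
    variables and classified by the fold's discriminant, for every
    component count in ``k_range``.  A fold whose selection is empty is
    recorded with ``predicted = -1`` ("no model"), never silently skipped.
    """
    config = config or PipelineConfig()
    labels = _check_dataset(runs, min_per_class=3)
    rows = []
    for i, heldout in enumerate(runs):
        training = [r for j, r in enumerate(runs) if j != i]
        try:
            fit = run_pipeline(training, config)
        except NoSignificantVariables:
            for k in k_range:
                rows.append((heldout.sample_id, k, 0, -1, int(labels[i])))
            continue
        train_labels = np.delete(labels, i)
        discriminants = {}
        for k in k_range:
            kk = min(k, fit.pca.n_components)
            discriminants[k] = discriminant_fit(fit.scores, train_labels, kk)
        preds = _predict_heldout(
            heldout, fit.config.grid(), config, fit.selection, fit.pca,
            discriminants,
        )
        for k in k_range:
            rows.append(
                (heldout.sample_id, k, fit.selection.n_expanded, preds[k],
                 int(labels[i]))
            )
    folds = pd.DataFrame(
        rows, columns=["sample_id", "k", "n_selected", "predicted", "true"]
    )
    return CVReport(folds)
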