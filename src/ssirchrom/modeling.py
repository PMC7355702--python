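"""PCA on selected variables, Fisher linear discriminant, and metrics.

The selected variables enter PCA with their pre-dichotomization intensity
sums as descriptor values.  Default preprocessing is autoscaling (unit
variance), i.e. an eigendecomposition of the correlation matrix; plain
centering (covariance matrix) is available via ``scaling_mode='center'``.
Classification uses a Fisher linear discriminant on the first k principal
component scores with a midpoint threshold between the class means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA as _SkPCA

__all__ = [
    "PCAModel",
    "DiscriminantModel",
    "MetricsReport",
    "pca_fit",
    "pca_transform",
    "discriminant_fit",
    "discriminant_predict",
    "evaluate",
]


@dataclass
class PCAModel:
    variable_ids: list
    center: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray  # (n_variables, n_components), orthonormal columns
    explained_variance: np.ndarray  # per-component eigenvalue
    explained_fraction: np.ndarray  # per-component fraction of total variance
    scaling_mode: str

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


@dataclass
class DiscriminantModel:
    """Linear discriminant on the first ``n_components`` score columns.

    A score vector s is classified as the positive class iff
    ``weights . s[:k] >= threshold``.
    """

    n_components: int
    weights: np.ndarray
    threshold: float
    positive_class: int = 1


@dataclass
class MetricsReport:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    def summary(self) -> str:
        return (
            f"n={self.n} TP={self.tp} TN={self.tn} FP={self.fp} FN={self.fn} "
            f"sensitivity={self.sensitivity:.3f} "
            f"specificity={self.specificity:.3f}"
        )


def _prepare(X: np.ndarray, scaling_mode: str, variable_ids):
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("descriptor matrix must be 2-D (samples x variables)")
    center = X.mean(axis=0)
    if scaling_mode == "autoscale":
        scale = X.std(axis=0, ddof=1)
        zero = np.nonzero(scale == 0)[0]
        if zero.size:
            vid = variable_ids[zero[0]] if variable_ids is not None else zero[0]
            raise ValueError(
                f"variable {vid!r} is constant; autoscaling is undefined "
                "(use scaling_mode='center' or drop it)"
            )
    elif scaling_mode == "center":
        scale = np.ones(X.shape[1])
    else:
        raise ValueError(f"unknown scaling_mode {scaling_mode!r}")
    return X, center, scale


def pca_fit(
    X: np.ndarray,
    scaling_mode: str = "autoscale",
    n_components: int | None = None,
    variable_ids: Sequence | None = None,
) -> PCAModel:
    """Principal components of the (scaled) descriptor matrix.

    Components are ordered by decreasing eigenvalue; each loading column's
    sign is fixed so its largest-magnitude entry is positive, making
    reports reproducible run-to-run.
    """
    if variable_ids is None:
        variable_ids = list(range(np.asarray(X).shape[1]))
    X, center, scale = _prepare(X, scaling_mode, list(variable_ids))
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    Z = (X - center) / scale
    max_rank = min(X.shape[0] - 1, X.shape[1])
    k = max_rank if n_components is None else min(n_components, max_rank)
    pca = _SkPCA(n_components=k, svd_solver="full")
    pca.fit(Z)
    loadings = pca.components_.T.copy()
    for j in range(loadings.shape[1]):
        pivot = np.argmax(np.abs(loadings[:, j]))
        if loadings[pivot, j] < 0:
            loadings[:, j] = -loadings[:, j]
    return PCAModel(
        list(variable_ids),
        center,
        scale,
        loadings,
        pca.explained_variance_.copy(),
        pca.explained_variance_ratio_.copy(),
        scaling_mode,
    )


def pca_transform(model: PCAModel, X: np.ndarray) -> np.ndarray:
    """Project samples onto the model's components (scores)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != len(model.variable_ids):
        raise ValueError(
            f"expected {len(model.variable_ids)} variables, got {X.shape[1]}"
        )
    return ((X - model.center) / model.scale) @ model.loadings


def discriminant_fit(
    scores: np.ndarray, labels: np.ndarray, n_components: int = 1
) -> DiscriminantModel:
    """Fisher linear discriminant on the first ``n_components`` scores.

    w is proportional to pooled-covariance^-1 (mean_1 - mean_0); the
    decision threshold is the midpoint w . (mean_1 + mean_0)/2.  With one
    component this reduces to a midpoint cut on that component.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = np.asarray(labels, dtype=int)
    if labels.shape[0] != scores.shape[0]:
        raise ValueError("scores and labels length mismatch")
    if not 1 <= n_components <= scores.shape[1]:
        raise ValueError(
            f"n_components must be in [1, {scores.shape[1]}]"
        )
    S = scores[:, :n_components]
    m1 = S[labels == 1]
    m0 = S[labels == 0]
    if len(m1) == 0 or len(m0) == 0:
        raise ValueError("both classes must be present")
    mu1, mu0 = m1.mean(axis=0), m0.mean(axis=0)
    delta = mu1 - mu0
    if np.allclose(delta, 0):
        raise ValueError("class means coincide; discriminant is degenerate")
    if len(m1) > 1 and len(m0) > 1:
        pooled = (
            (len(m1) - 1) * np.cov(m1, rowvar=False).reshape(n_components, -1)
            + (len(m0) - 1) * np.cov(m0, rowvar=False).reshape(n_components, -1)
        ) / (len(m1) + len(m0) - 2)
    else:
        pooled = np.eye(n_components)
    try:
        w = np.linalg.solve(pooled, delta)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "pooled covariance is singular; try fewer components"
        ) from exc
    threshold = float(w @ (mu1 + mu0) / 2.0)
    return DiscriminantModel(n_components, w, threshold)


def discriminant_predict(model: DiscriminantModel, scores: np.ndarray) -> np.ndarray:
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    proj = scores[:, : model.n_components] @ model.weights
    pred = np.where(proj >= model.threshold, model.positive_class,
                    1 - model.positive_class)
    return pred.astype(int)


def evaluate(predictions: np.ndarray, labels: np.ndarray) -> MetricsReport:
    """Confusion counts with class 1 (treated) as the positive class."""
    predictions = np.asarray(predictions, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must have equal length")
    seen = set(np.unique(predictions)) | set(np.unique(labels))
    if not seen <= {0, 1}:
        raise ValueError(f"unexpected label values {sorted(seen - {0, 1})}")
    tp = int(np.sum((predictions == 1) & (labels == 1)))
    tn = int(np.sum((predictions == 0) & (labels == 0)))
    fp = int(np.sum((predictions == 1) & (labels == 0)))
    fn = int(np.sum((predictions == 0) & (labels == 1)))
    return MetricsReport(tp, tn, fp, fn)
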