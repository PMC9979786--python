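"""k-nearest-neighbor gaze classifier over flattened epochs.

A test epoch is assigned the majority class among its k nearest training
exemplars. Tie-break chain, fully deterministic: (1) majority count,
(2) larger summed inverse distance among the tied classes, (3) fixed
class order (D, L, N, R, U, B).

Implemented directly (distance matrix + argpartition) rather than on a
library estimator because the tie-break contract above is part of the
classifier's definition; library kNN serves as a cross-check in tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .types import CLASS_ORDER, EpochSet, ValidationError

_METRICS = {"euclidean", "cityblock", "chebyshev", "cosine"}


@dataclass(frozen=True)
class KNNConfig:
    """k and the distance metric; defaults k=5, Euclidean distance."""

    k: int = 5
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValidationError(f"k must be >= 1, got {self.k}")
        if self.metric not in _METRICS:
            raise ValidationError(
                f"metric {self.metric!r} not supported; choose from {sorted(_METRICS)}"
            )


def _flatten(X: np.ndarray | EpochSet) -> np.ndarray:
    arr = X.X if isinstance(X, EpochSet) else np.asarray(X, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    return arr.reshape(len(arr), -1)


class KNNClassifier:
    """Exemplar-memory classifier; stores the training set verbatim."""

    def __init__(self, config: KNNConfig | None = None):
        self.config = config or KNNConfig()
        self._X: np.ndarray | None = None
        self._y: np.ndarray | None = None

    @property
    def n_exemplars(self) -> int:
        return 0 if self._X is None else len(self._X)

    def fit(self, X: np.ndarray | EpochSet, y: np.ndarray | None = None) -> "KNNClassifier":
        if isinstance(X, EpochSet):
            y = X.y
        if y is None:
            raise ValidationError("labels required to fit")
        flat = _flatten(X)
        if self.config.k > len(flat):
            raise ValidationError(
                f"k={self.config.k} exceeds training-set size {len(flat)}"
            )
        self._X = flat.copy()
        self._y = np.asarray(y, dtype=object).copy()
        return self

    def _vote(self, dists: np.ndarray) -> str:
        k = self.config.k
        assert self._y is not None
        if k < len(dists):
            nn = np.argpartition(dists, k - 1)[:k]
        else:
            nn = np.arange(len(dists))
        labels = self._y[nn]
        d = dists[nn]
        counts: dict[str, int] = {}
        inv: dict[str, float] = {}
        for lab, dist in zip(labels, d):
            counts[lab] = counts.get(lab, 0) + 1
            inv[lab] = inv.get(lab, 0.0) + 1.0 / (dist + 1e-12)
        best = max(counts.values())
        tied = [c for c, n in counts.items() if n == best]
        if len(tied) > 1:
            best_inv = max(inv[c] for c in tied)
            tied = [c for c in tied if inv[c] == best_inv]
        if len(tied) > 1:
            tied.sort(key=CLASS_ORDER.index)
        return tied[0]

    def predict(self, X: np.ndarray | EpochSet) -> np.ndarray:
        if self._X is None or self._y is None:
            raise ValidationError("KNNClassifier is not fitted")
        queries = _flatten(X)
        dmat = cdist(queries, self._X, metric=self.config.metric)
        return np.array([self._vote(row) for row in dmat], dtype=object)


def sweep_k(
    train: EpochSet,
    val: EpochSet,
    ks: tuple[int, ...] = (1, 3, 5, 7, 9, 11, 13, 15),
    metric: str = "euclidean",
) -> dict[int, float]:
    """Validation accuracy for each candidate k (metric held fixed)."""
    out = {}
    for k in ks:
        model = KNNClassifier(KNNConfig(k=k, metric=metric)).fit(train)
        out[k] = float(np.mean(model.predict(val) == val.y))
    return out


def sweep_metric(
    train: EpochSet,
    val: EpochSet,
    metrics: tuple[str, ...] = ("euclidean", "cityblock", "chebyshev"),
    k: int = 5,
) -> dict[str, float]:
    """Validation accuracy for each candidate metric (k held fixed)."""
    out = {}
    for m in metrics:
        model = KNNClassifier(KNNConfig(k=k, metric=m)).fit(train)
        out[m] = float(np.mean(model.predict(val) == val.y))
    return out
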