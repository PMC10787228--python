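"""Nearest-centroid classification on discriminative Mueller elements.

The three elements m23, m32 and m44 separate the four diagnostic classes:
m23 and m44 decrease monotonically from healthy through benign, grade-2 and
grade-3 tissue while m32 increases.  A nearest-centroid rule over those
elements (standardized by per-class spreads) is the minimal classifier
consistent with that ordering; the reference model uses the built-in class
profiles as centroids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mueller import ElementAverages
from .profiles import CLASS_LABELS, ClassProfile, builtin_profiles, element_index

__all__ = [
    "DEFAULT_FEATURES",
    "CentroidModel",
    "fit_centroids",
    "reference_model",
    "classify_sample",
    "confusion_matrix",
]

DEFAULT_FEATURES: tuple[str, ...] = ("m23", "m32", "m44")

# floor for standardizing scales so zero-variance training data stays usable
_SCALE_FLOOR = 1e-9


@dataclass(frozen=True)
class CentroidModel:
    """Per-class centroids (and scales) over a fixed element feature set."""

    features: tuple[str, ...]
    centroids: dict[str, np.ndarray]
    scales: dict[str, np.ndarray] | None = None
    standardized: bool = True

    def __post_init__(self) -> None:
        if len(self.centroids) < 2:
            raise ValueError("need at least two classes")
        k = len(self.features)
        for lbl, c in self.centroids.items():
            if np.asarray(c).shape != (k,):
                raise ValueError(f"centroid for {lbl!r} must have {k} components")

    @property
    def class_order(self) -> list[str]:
        """Fixed deterministic class order (canonical labels first)."""
        known = [c for c in CLASS_LABELS if c in self.centroids]
        extra = sorted(c for c in self.centroids if c not in CLASS_LABELS)
        return known + extra


def fit_centroids(
    training: list[ElementAverages],
    features: tuple[str, ...] = DEFAULT_FEATURES,
    standardized: bool = True,
) -> CentroidModel:
    """Per-class mean (and std) of the selected features from labeled data."""
    idx = [element_index(f) for f in features]
    by_label: dict[str, list[np.ndarray]] = {}
    for s in training:
        if s.label is None:
            raise ValueError(f"sample {s.sample_id!r} has no class label")
        by_label.setdefault(s.label, []).append(s.values[idx])
    if not by_label:
        raise ValueError("no training samples")
    centroids = {}
    scales = {}
    for lbl, rows in by_label.items():
        X = np.stack(rows)
        centroids[lbl] = X.mean(axis=0)
        scales[lbl] = (
            X.std(axis=0, ddof=1) if len(rows) > 1 else np.zeros(len(features))
        )
    return CentroidModel(
        features=tuple(features),
        centroids=centroids,
        scales=scales,
        standardized=standardized,
    )


def reference_model(
    features: tuple[str, ...] = DEFAULT_FEATURES,
    profiles: dict[str, ClassProfile] | None = None,
    standardized: bool = True,
) -> CentroidModel:
    """Centroid model built from the built-in class profiles."""
    if profiles is None:
        profiles = builtin_profiles()
    idx = [element_index(f) for f in features]
    return CentroidModel(
        features=tuple(features),
        centroids={lbl: p.element_mean[idx].copy() for lbl, p in profiles.items()},
        scales={lbl: p.element_std[idx].copy() for lbl, p in profiles.items()},
        standardized=standardized,
    )


def classify_sample(
    features: np.ndarray | ElementAverages, model: CentroidModel
) -> tuple[str, dict[str, float]]:
    """Assign the nearest centroid; return (label, distance per class).

    Distances are Euclidean, optionally standardized by per-class scales.
    Ties break deterministically in the fixed class order
    healthy < benign < grade2 < grade3.
    """
    if isinstance(features, ElementAverages):
        idx = [element_index(f) for f in model.features]
        x = features.values[idx]
    else:
        x = np.asarray(features, float)
    if x.shape != (len(model.features),):
        raise ValueError(
            f"expected {len(model.features)} features, got shape {x.shape}"
        )
    if not np.isfinite(x).all():
        raise ValueError("non-finite feature values")
    distances: dict[str, float] = {}
    for lbl in model.class_order:
        diff = x - np.asarray(model.centroids[lbl], float)
        if model.standardized and model.scales is not None:
            scale = np.maximum(np.asarray(model.scales[lbl], float), _SCALE_FLOOR)
            diff = diff / scale
        distances[lbl] = float(np.sqrt((diff**2).sum()))
    best = min(model.class_order, key=lambda lbl: (distances[lbl],))
    return best, distances


def confusion_matrix(
    true_labels: list[str], predicted: list[str], labels: list[str] | None = None
) -> pd.DataFrame:
    """Confusion matrix (rows: true class, columns: predicted).

    Row sums equal per-class sample counts by construction.
    """
    if len(true_labels) != len(predicted):
        raise ValueError("label lists must have equal length")
    if labels is None:
        seen = set(true_labels) | set(predicted)
        labels = [c for c in CLASS_LABELS if c in seen] + sorted(
            seen - set(CLASS_LABELS)
        )
    mat = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for t, p in zip(true_labels, predicted):
        mat.loc[t, p] += 1
    return mat
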