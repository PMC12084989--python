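"""Clustering validity indices of the health space, groups as clusters.

Silhouette, Davies-Bouldin and Calinski-Harabasz are computed on the 2-D
scores with the ordinal outcome groups as the (given, never inferred)
cluster labels, Euclidean metric throughout. The numerical work is
delegated to scikit-learn; this module adds the validation and degenerate
-case conventions used in the reports: a single group is an error,
exactly coincident centroids make Davies-Bouldin undefined (error naming
the pair), zero within-cluster dispersion yields an infinite
Calinski-Harabasz with a warning, and singleton clusters contribute a
silhouette of 0 (scikit-learn's convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn import metrics as _skm

__all__ = ["MetricsReport", "silhouette", "davies_bouldin", "calinski_harabasz", "metrics_report"]


def _validate(points, labels, min_groups: int = 2):
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    if points.ndim != 2 or points.shape[0] != labels.shape[0]:
        raise ValueError("points must be 2-d with one row per label")
    groups = np.unique(labels)
    if groups.size < min_groups:
        raise ValueError(
            "Silhouette undefined for one cluster"
            if min_groups == 2
            else "need at least 2 groups"
        )
    return points, labels, groups


def silhouette(points, labels) -> float:
    """Mean silhouette coefficient (b - a) / max(a, b), in [-1, 1]."""
    points, labels, _ = _validate(points, labels)
    if points.shape[0] < 3:
        raise ValueError("silhouette needs at least 3 samples")
    return float(_skm.silhouette_score(points, labels, metric="euclidean"))


def davies_bouldin(points, labels) -> float:
    """Davies-Bouldin index: mean worst-pair (s_i + s_j) / d(c_i, c_j)."""
    points, labels, groups = _validate(points, labels)
    centroids = np.array([points[labels == g].mean(axis=0) for g in groups])
    for a in range(len(groups)):
        for b in range(a + 1, len(groups)):
            if np.allclose(centroids[a], centroids[b], atol=0.0):
                raise ValueError(
                    f"clusters {groups[a]!r} and {groups[b]!r} have coincident "
                    "centroids; Davies-Bouldin is infinite"
                )
    return float(_skm.davies_bouldin_score(points, labels))


def calinski_harabasz(points, labels) -> float:
    """Calinski-Harabasz: [tr(B)/(k-1)] / [tr(W)/(n-k)], higher is better."""
    points, labels, groups = _validate(points, labels)
    n, k = points.shape[0], groups.size
    if n <= k:
        raise ValueError("Calinski-Harabasz needs n > number of groups")
    intra = sum(
        float(((points[labels == g] - points[labels == g].mean(axis=0)) ** 2).sum())
        for g in groups
    )
    if intra == 0.0:
        warnings.warn(
            "zero within-cluster dispersion; Calinski-Harabasz is infinite",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("inf")
    return float(_skm.calinski_harabasz_score(points, labels))


@dataclass(frozen=True)
class MetricsReport:
    """The three validity indices of one scored cohort."""

    silhouette: float
    davies_bouldin: float
    calinski_harabasz: float
    n_samples: int
    n_groups: int

    def to_dict(self) -> dict:
        return {
            "silhouette": self.silhouette,
            "davies_bouldin": self.davies_bouldin,
            "calinski_harabasz": self.calinski_harabasz,
            "n_samples": self.n_samples,
            "n_groups": self.n_groups,
        }


def metrics_report(points, labels) -> MetricsReport:
    points, labels, groups = _validate(points, labels)
    return MetricsReport(
        silhouette=silhouette(points, labels),
        davies_bouldin=davies_bouldin(points, labels),
        calinski_harabasz=calinski_harabasz(points, labels),
        n_samples=points.shape[0],
        n_groups=groups.size,
    )
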