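"""Clustering-quality and structural-similarity metrics.

External metrics (ARI, NMI) compare a clustering to ground-truth labels;
internal metrics (silhouette coefficient, Davies-Bouldin index) score
cluster cohesion versus separation from the data alone; corr2 is the
Pearson correlation of two equally-shaped matrices flattened to vectors,
used to check that imputation preserves overall co-expression structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn import metrics as _skm
from sklearn.cluster import KMeans

from scirt.expression_io import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ClusteringResult:
    """K-means output: per-cell assignment, cluster count, within-cluster SS."""

    assignments: np.ndarray
    k: int
    inertia: float

    def __post_init__(self) -> None:
        self.assignments = np.asarray(self.assignments, dtype=int)


def kmeans_cluster(
    matrix: np.ndarray, k: int, seed: int = 0, n_restarts: int = 10
) -> ClusteringResult:
    """Seeded k-means (rows = cells), best of ``n_restarts`` by inertia."""
    matrix = np.asarray(matrix, dtype=float)
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > matrix.shape[0]:
        raise ValidationError(f"k={k} exceeds the number of cells {matrix.shape[0]}")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    assignments = km.fit_predict(matrix)
    return ClusteringResult(assignments=assignments, k=k, inertia=float(km.inertia_))


def _check_same_length(a, b) -> tuple[np.ndarray, np.ndarray]:
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("label sequences must be 1-D and equal length")
    return a, b


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Pair-counting Rand index with expected-index correction; 1 = identical."""
    a, b = _check_same_length(labels_a, labels_b)
    return float(_skm.adjusted_rand_score(a, b))


def normalized_mutual_information(
    labels_a, labels_b, average_method: str = "arithmetic"
) -> float:
    """Mutual information normalized by the (arithmetic-mean) entropies."""
    a, b = _check_same_length(labels_a, labels_b)
    return float(_skm.normalized_mutual_info_score(a, b, average_method=average_method))


def silhouette_coefficient(matrix: np.ndarray, assignments) -> float:
    """Mean silhouette (b - a)/max(a, b) over cells, euclidean distances.

    Cells in singleton clusters contribute 0 (with a warning), matching
    the usual convention for undefined intra-cluster distances.
    """
    matrix = np.asarray(matrix, dtype=float)
    assignments = np.asarray(assignments)
    labels, counts = np.unique(assignments, return_counts=True)
    if labels.size < 2:
        raise ValidationError("silhouette needs at least 2 clusters")
    if np.any(counts == 1):
        logger.warning(
            "%d singleton cluster(s): their cells' silhouette is 0", int((counts == 1).sum())
        )
    return float(_skm.silhouette_score(matrix, assignments, metric="euclidean"))


def davies_bouldin_index(matrix: np.ndarray, assignments) -> float:
    """Mean over clusters of the worst (s_i + s_j) / d_ij ratio; lower is better.

    s_i is the mean distance of cluster i's points to its centroid and
    d_ij the centroid separation. Coincident centroids are epsilon-guarded.
    """
    matrix = np.asarray(matrix, dtype=float)
    assignments = np.asarray(assignments)
    labels = np.unique(assignments)
    if labels.size < 2:
        raise ValidationError("Davies-Bouldin needs at least 2 clusters")
    centroids = np.stack([matrix[assignments == lab].mean(axis=0) for lab in labels])
    scatter = np.array(
        [
            np.mean(np.linalg.norm(matrix[assignments == lab] - centroids[i], axis=1))
            for i, lab in enumerate(labels)
        ]
    )
    sep = np.linalg.norm(centroids[:, None, :] - centroids[None, :, :], axis=2)
    if np.any(sep[~np.eye(labels.size, dtype=bool)] == 0):
        logger.warning("coincident cluster centroids: ratio epsilon-guarded")
    ratios = (scatter[:, None] + scatter[None, :]) / np.maximum(sep, 1e-12)
    np.fill_diagonal(ratios, -np.inf)
    return float(np.mean(ratios.max(axis=1)))


def corr2(matrix_a: np.ndarray, matrix_b: np.ndarray) -> float:
    """Pearson correlation of two equally-shaped matrices after flattening."""
    a = np.asarray(matrix_a, dtype=float)
    b = np.asarray(matrix_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("matrices must have identical shapes")
    a, b = a.ravel(), b.ravel()
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValidationError("corr2 is undefined for a constant matrix")
    return float(np.corrcoef(a, b)[0, 1])
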