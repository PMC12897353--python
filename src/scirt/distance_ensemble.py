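"""Ensemble cell-cell distances aggregated at the rank level.

Single distance metrics emphasize different data features and none is
reliably best across datasets, so cell similarity is measured by computing
several metrics, converting each distance matrix to an ordinal (rank)
matrix per cell, and summing the rank matrices with per-metric weights
into one consensus matrix M = sum_n t_n * R^n. Ranks absorb any monotone
rescaling of an individual metric, which is what makes metrics on
different scales commensurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from scirt.expression_io import ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_METRICS: tuple[str, ...] = ("euclidean", "pearson", "spearman", "cosine")


@dataclass
class DistanceMatrix:
    """y x y dissimilarity matrix under one metric; zero diagonal, finite."""

    values: np.ndarray
    metric_name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValidationError("distance matrix must be square")


@dataclass
class RankMatrix:
    """Per-cell similarity ordering: row i ranks all cells by similarity to cell i.

    Every row is a permutation of 1..y with the diagonal (self) forced to 1.
    """

    values: np.ndarray
    metric_name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=int)


@dataclass
class ConsensusMatrix:
    """Weighted elementwise sum of rank matrices; smaller means more similar."""

    values: np.ndarray
    weights: list[float] = field(default_factory=list)


def _correlation_distance(values: np.ndarray, kind: str) -> np.ndarray:
    """1 - correlation, with undefined pairs (constant vectors) set to 2."""
    data = values
    if kind == "spearman":
        data = rankdata(values, axis=1)
    sd = data.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "%d constant cell vector(s): correlation undefined, distance set to 2",
            int(constant.sum()),
        )
    centered = data - data.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    safe = np.where(norms == 0, 1.0, norms)
    unit = centered / safe[:, None]
    corr = np.clip(unit @ unit.T, -1.0, 1.0)
    dist = 1.0 - corr
    bad = constant[:, None] | constant[None, :]
    dist[bad] = 2.0
    np.fill_diagonal(dist, 0.0)
    return dist


def pairwise_distance(matrix: ExpressionMatrix, metric: str) -> DistanceMatrix:
    """Cell-cell dissimilarity matrix under one metric.

    ``euclidean`` and ``cosine`` come from scipy's pdist; ``pearson`` and
    ``spearman`` are 1 - correlation with constant-vector pairs assigned
    the maximum dissimilarity 2 (and a warning).
    """
    values = matrix.values
    if values.shape[0] < 2:
        raise ValidationError("need at least 2 cells for pairwise distances")
    if metric == "euclidean":
        dist = squareform(pdist(values, metric="euclidean"))
    elif metric == "cosine":
        zero = np.linalg.norm(values, axis=1) == 0
        if zero.any():
            logger.warning(
                "%d zero cell vector(s): cosine undefined, distance set to 2",
                int(zero.sum()),
            )
            safe = values.copy()
            safe[zero] = 1.0  # placeholder rows, overwritten below
            dist = squareform(pdist(safe, metric="cosine"))
            bad = zero[:, None] | zero[None, :]
            dist[bad] = 2.0
            np.fill_diagonal(dist, 0.0)
        else:
            dist = squareform(pdist(values, metric="cosine"))
    elif metric in ("pearson", "spearman"):
        dist = _correlation_distance(values, metric)
    else:
        raise ValidationError(f"unknown metric {metric!r}")
    return DistanceMatrix(dist, metric_name=metric)


def rank_rows(dist: DistanceMatrix) -> RankMatrix:
    """Convert each distance row to a similarity ordering with self at rank 1.

    The cell itself always gets rank 1 (a cell is most similar to itself);
    the remaining cells are ranked 2..y by ascending distance, ties broken
    by lower cell index.
    """
    d = dist.values
    y = d.shape[0]
    ranks = np.empty((y, y), dtype=int)
    idx = np.arange(y)
    for i in range(y):
        row = d[i].copy()
        row[i] = -np.inf  # self first regardless of stored diagonal
        # lexsort: primary ascending distance, secondary ascending index
        order = np.lexsort((idx, row))
        ranks[i, order] = idx + 1
    return RankMatrix(ranks, metric_name=dist.metric_name)


def aggregate_ranks(
    ranks: list[RankMatrix], weights: list[float] | None = None
) -> ConsensusMatrix:
    """Weighted elementwise sum M = sum_n t_n * R^n. Default weights are all 1."""
    if not ranks:
        raise ValidationError("need at least one rank matrix")
    if weights is None:
        weights = [1.0] * len(ranks)
    if len(weights) != len(ranks):
        raise ValidationError(
            f"{len(weights)} weights for {len(ranks)} rank matrices"
        )
    shape = ranks[0].values.shape
    for r in ranks:
        if r.values.shape != shape:
            raise ValidationError("rank matrices must share a shape")
    total = np.zeros(shape, dtype=float)
    for t, r in zip(weights, ranks):
        total += t * r.values
    return ConsensusMatrix(total, weights=list(map(float, weights)))


def consensus_matrix(
    matrix: ExpressionMatrix,
    metrics: tuple[str, ...] = DEFAULT_METRICS,
    weights: list[float] | None = None,
) -> ConsensusMatrix:
    """One-call ensemble: distances -> per-metric ranks -> weighted rank sum."""
    rank_mats = [rank_rows(pairwise_distance(matrix, m)) for m in metrics]
    return aggregate_ranks(rank_mats, weights)


def similarity_orderings(consensus: ConsensusMatrix) -> np.ndarray:
    """Per-cell orderings of all cells by consensus similarity (target first).

    Row i lists cell indices from most to least similar to cell i; cell i
    itself is placed first and ties are broken by lower cell index.
    """
    m = consensus.values
    y = m.shape[0]
    idx = np.arange(y)
    orderings = np.empty((y, y), dtype=int)
    for i in range(y):
        row = m[i].copy()
        row[i] = -np.inf
        orderings[i] = np.lexsort((idx, row))
    return orderings
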