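"""SMOTE-style random imputation of cells from their consensus neighbors.

Each cell a_i is replaced by a convex blend

    a_i* = (1 - RE) * a_i + sum_{j != i} f_ij * a_j

where the external weights f_ij sum exactly to RE (the total mass of
information borrowed from other cells; RE = 0 keeps the cell unchanged).
Raw weights follow the geometric pmf (1-p)^(x-1) p evaluated along the
consensus similarity ranking, so with small p many neighbors contribute
and with p near 1 only the nearest few do. To avoid overfitting to the
single nearest neighbor the pmf values are randomly shuffled among cells
of similar rank (within blocks of ``window`` consecutive ranks) before
normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from scirt.distance_ensemble import ConsensusMatrix, similarity_orderings
from scirt.expression_io import ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_RE = 0.9
DEFAULT_WINDOW = 4


@dataclass
class WeightAssignment:
    """External blend weights for one target cell.

    ``weights[j]`` is f_ij for cell j; the target's own entry is 0 and the
    external entries sum to ``re`` (to 1e-12). The implicit full blend row
    is (1 - re) at the target plus these weights, summing to 1.
    """

    weights: np.ndarray
    re: float
    target: int

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ValidationError("weights must be non-negative")
        if self.weights[self.target] != 0:
            raise ValidationError("target's external weight must be 0")
        total = self.weights.sum()
        if abs(total - self.re) > 1e-9:
            raise ValidationError(
                f"external weights sum to {total}, expected RE={self.re}"
            )


def geometric_pmf(p: float, x: int | np.ndarray) -> float | np.ndarray:
    """Geometric pmf P(X = x) = (1-p)^(x-1) p on support x = 1, 2, 3, ..."""
    if not 0.0 < p <= 1.0:
        raise ValidationError(f"p must be in (0, 1], got {p}")
    x = np.asarray(x)
    if np.any(x < 1):
        raise ValidationError("geometric support is x >= 1")
    out = (1.0 - p) ** (x - 1) * p
    return float(out) if out.ndim == 0 else out


def layer_parameter(num_clusters: int, shrink: float, y: int) -> float:
    """Geometric parameter p = NUM / (shrink * y) for the flat top layer.

    The expected value 1/p = shrink*y/NUM is the (shrunk) average cluster
    size, so a draw from this law spreads weight over a whole cluster's
    worth of neighbors. Clamped to (0, 1] with a warning if the cluster
    count exceeds the shrunk cell count.
    """
    if num_clusters < 1:
        raise ValidationError("num_clusters must be >= 1")
    if y < num_clusters:
        raise ValidationError(f"y={y} must be >= num_clusters={num_clusters}")
    if not 0.0 < shrink <= 1.0:
        raise ValidationError(f"shrink must be in (0, 1], got {shrink}")
    p = num_clusters / (shrink * y)
    if p > 1.0:
        logger.warning("layer parameter p=%.4f > 1, clamping to 1", p)
        p = 1.0
    return p


def sample_weights(
    ordering: np.ndarray,
    p: float,
    re: float = DEFAULT_RE,
    window: int = DEFAULT_WINDOW,
    rng: np.random.Generator | None = None,
) -> WeightAssignment:
    """Draw randomized geometric weights for one target cell.

    Parameters
    ----------
    ordering : int array of length y
        Cell indices from most to least similar to the target; the target
        itself is first.
    p : float in (0, 1]
        Geometric parameter; the nearest neighbor's raw weight is pmf(1) = p.
    re : float in [0, 1]
        Total external mass; raw weights are rescaled to sum exactly to it.
    window : int >= 1
        Size of the rank blocks within which pmf values are shuffled
        ("similarly ranked" cells may swap weights). ``window=1`` disables
        the shuffle, making weights deterministic and monotone in rank.
    rng : numpy Generator
        Source of randomness for the within-block shuffle.
    """
    if not 0.0 <= re <= 1.0:
        raise ValidationError(f"RE must be in [0, 1], got {re}")
    if window < 1:
        raise ValidationError("window must be >= 1")
    ordering = np.asarray(ordering, dtype=int)
    y = ordering.size
    target = int(ordering[0])
    weights = np.zeros(y, dtype=float)
    if y == 1 or re == 0.0:
        return WeightAssignment(weights, re=re, target=target)
    if rng is None:
        rng = np.random.default_rng()

    x = np.arange(1, y, dtype=int)  # pmf argument for similarity ranks 2..y
    if window > 1:
        x = x.copy()
        for start in range(0, y - 1, window):
            block = x[start : start + window]
            rng.shuffle(block)
    raw = geometric_pmf(p, x)
    raw_sum = raw.sum()
    weights[ordering[1:]] = raw * (re / raw_sum)
    return WeightAssignment(weights, re=re, target=target)


def impute_cell(
    a_i: np.ndarray, weights: WeightAssignment, matrix: ExpressionMatrix
) -> np.ndarray:
    """Blend one cell with the rest of the matrix: (1-RE) a_i + sum f_ij a_j."""
    a_i = np.asarray(a_i, dtype=float)
    if weights.weights.size != matrix.n_cells:
        raise ValidationError("weight vector length must equal cell count")
    return (1.0 - weights.re) * a_i + weights.weights @ matrix.values


def impute_layer(
    matrix: ExpressionMatrix,
    consensus: ConsensusMatrix,
    p: float,
    re: float = DEFAULT_RE,
    window: int = DEFAULT_WINDOW,
    rng: np.random.Generator | None = None,
) -> ExpressionMatrix:
    """One synchronous imputation round over all cells.

    Weights for every cell are sampled from its consensus similarity
    ordering, assembled into a row-stochastic blend matrix W (diagonal
    1-RE, off-diagonal f_ij) and applied as a single matrix product
    W @ A, so every update reads the pre-layer matrix.
    """
    y = matrix.n_cells
    if consensus.values.shape != (y, y):
        raise ValidationError("consensus shape does not match cell count")
    if rng is None:
        rng = np.random.default_rng()
    orderings = similarity_orderings(consensus)
    W = np.zeros((y, y), dtype=float)
    for i in range(y):
        wa = sample_weights(orderings[i], p=p, re=re, window=window, rng=rng)
        W[i] = wa.weights
        W[i, i] = 1.0 - re
    imputed = W @ matrix.values
    np.maximum(imputed, 0.0, out=imputed)  # guard float undershoot at 0
    return ExpressionMatrix(imputed, list(matrix.cell_ids), list(matrix.gene_ids))
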