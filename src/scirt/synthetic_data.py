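"""Cluster-structured synthetic count matrices and the dropout-masking protocol.

The generator draws negative-binomial counts with per-cluster differentially
expressed (DE) gene sets, giving cluster-separable data with known labels.
The masker implements the artificial-dropout protocol used to benchmark
imputation tools: choose an exact fraction of matrix elements uniformly at
random and set them to zero, recording the mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from scirt.expression_io import CellLabels, ExpressionMatrix, ValidationError


@dataclass
class SimulationConfig:
    """Parameters of the negative-binomial cluster simulator.

    Attributes
    ----------
    n_cells, n_genes, n_clusters : int
        Matrix dimensions and number of cell types; cells are split across
        clusters as evenly as possible.
    de_fraction : float in [0, 1]
        Fraction of genes differentially expressed in each cluster; each
        cluster draws its own DE gene set independently.
    effect_size : float > 1
        Multiplicative mean shift applied to a cluster's DE genes.
    base_mean : float
        Baseline per-gene negative-binomial mean (gene means are jittered
        around it log-normally to mimic a realistic mean spectrum).
    dispersion : float
        Negative-binomial shape r; variance = mu + mu^2 / r, so smaller r
        means more overdispersion.
    seed : int
        Seed for bit-reproducible generation.
    """

    n_cells: int = 300
    n_genes: int = 500
    n_clusters: int = 3
    de_fraction: float = 0.2
    effect_size: float = 8.0
    base_mean: float = 1.0
    dispersion: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 1 or self.n_genes < 1 or self.n_clusters < 1:
            raise ValidationError("n_cells, n_genes and n_clusters must be positive")
        if self.n_clusters > self.n_cells:
            raise ValidationError(
                f"n_clusters={self.n_clusters} exceeds n_cells={self.n_cells}"
            )
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValidationError(f"de_fraction must be in [0, 1], got {self.de_fraction}")
        if self.effect_size < 1.0:
            raise ValidationError(f"effect_size must be >= 1, got {self.effect_size}")
        if self.base_mean <= 0 or self.dispersion <= 0:
            raise ValidationError("base_mean and dispersion must be positive")


def generate_clustered_counts(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, CellLabels]:
    """Draw a cluster-structured count matrix with known labels.

    Each gene g gets a baseline mean ``mu_g`` (log-normal around
    ``base_mean``); cluster c multiplies the means of its own DE gene set
    by ``effect_size``. Counts are NB(r=dispersion, mean=mu) draws,
    independent across entries. Cells are assigned to clusters in
    contiguous, as-even-as-possible blocks.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    y, s, k = config.n_cells, config.n_genes, config.n_clusters

    # log-normal jitter (sigma = 0.5) around base_mean gives a spread of
    # gene means without changing the overall scale much
    mu = config.base_mean * rng.lognormal(mean=0.0, sigma=0.5, size=s)

    n_de = int(round(config.de_fraction * s))
    cluster_mu = np.tile(mu, (k, 1))
    for c in range(k):
        de_genes = rng.choice(s, size=n_de, replace=False)
        cluster_mu[c, de_genes] *= config.effect_size

    sizes = np.full(k, y // k)
    sizes[: y % k] += 1
    assignments = np.repeat(np.arange(k), sizes)

    r = config.dispersion
    means = cluster_mu[assignments]  # y x s
    p = r / (r + means)
    counts = rng.negative_binomial(r, p).astype(float)

    matrix = ExpressionMatrix(counts)
    labels = CellLabels([f"type{c}" for c in assignments])
    return matrix, labels


def apply_dropout(
    matrix: ExpressionMatrix,
    rate: float,
    seed: int = 0,
    nonzero_only: bool = False,
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Zero an exact uniformly-random fraction of matrix elements.

    Exactly ``round(rate * n_cells * n_genes)`` positions are chosen without
    replacement over all elements (zeros included, so masking an
    already-zero entry is a value no-op but is still recorded in the mask).
    With ``nonzero_only=True`` the draw is restricted to currently nonzero
    entries instead, masking ``round(rate * #nonzero)`` of them.

    Returns
    -------
    (masked_matrix, mask)
        ``mask`` is a boolean cells x genes array marking zeroed positions;
        entries outside the mask are bit-identical to the input.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValidationError(f"dropout rate must be in [0, 1], got {rate}")
    rng = np.random.default_rng(seed)
    values = matrix.values.copy()
    mask = np.zeros(values.shape, dtype=bool)
    if nonzero_only:
        candidates = np.flatnonzero(values.ravel() != 0)
    else:
        candidates = np.arange(values.size)
    n_mask = int(round(rate * candidates.size))
    if n_mask > 0:
        chosen = rng.choice(candidates, size=n_mask, replace=False)
        flat_mask = mask.ravel()
        flat_mask[chosen] = True
        mask = flat_mask.reshape(values.shape)
        values[mask] = 0.0
    return ExpressionMatrix(values, list(matrix.cell_ids), list(matrix.gene_ids)), mask
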