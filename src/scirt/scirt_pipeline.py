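"""The multi-layer imputation pipeline.

Layer schedule: with y cells and nc expected cell types, the number of
layers is mean_number = floor(log2(y/nc)). Layer l (1-based) imputes with
geometric parameter p = 1/2^l, so early layers concentrate weight on the
2, 4, 8, ... nearest neighbors (roughly: cells of the target's own type)
and later layers spread it wider; the top layer uses the flat parameter
p = nc/y whose expected value is the average cluster size, weighting all
of a cluster's worth of neighbors near-equally. After each layer's
imputation the matrix is replaced by its rank-k NMF reconstruction, a
low-rank constraint that pulls the layer toward a k-type structure; the
RMS residual of that reconstruction is logged per layer. A final NMF of
the last layer's reconstruction yields the outputs: the imputed
high-dimensional matrix Z @ H (cells x genes) and the low-dimensional
representation Z (cells x k) used for clustering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from scirt.distance_ensemble import DEFAULT_METRICS, consensus_matrix
from scirt.expression_io import ExpressionMatrix, ValidationError
from scirt.nmf_engine import NmfConfig, nmf_factorize
from scirt.smote_imputer import DEFAULT_RE, DEFAULT_WINDOW, impute_layer, layer_parameter


@dataclass
class LayerSchedule:
    """Per-layer geometric parameters of the multi-layer framework.

    Attributes
    ----------
    mean_number : int
        Number of layers, floor(log2(y / nc)).
    times : tuple of int
        Neighborhood sizes (2, 4, ..., 2^mean_number); layer l's geometric
        law has expected value times[l].
    eec : int
        Expected cells per cluster after shrinkage, floor(y/nc * shrink).
    p_schedule : tuple of float
        Geometric parameter per layer: 1/times[l] while times[l] <= eec,
        and the flat nc/y at the top layer.
    shrink : float
        Shrinkage coefficient applied to the average cluster size.
    """

    mean_number: int
    times: tuple[int, ...]
    eec: int
    p_schedule: tuple[float, ...]
    shrink: float


@dataclass
class ScirtConfig:
    """Pipeline settings; defaults follow the method's published choices."""

    re: float = DEFAULT_RE
    shrink: float = 0.9
    window: int = DEFAULT_WINDOW
    k: int | None = None  # None -> nc
    metrics: tuple[str, ...] = DEFAULT_METRICS
    metric_weights: list[float] | None = None
    noise_model: str = "gaussian"
    nmf_max_iter: int = 200
    nmf_tol: float = 1e-4
    freeze_ranks: bool = False
    keep_layers: bool = False  # retain each layer's reconstruction in the result
    seed: int = 0


@dataclass
class ScirtResult:
    """Pipeline outputs: imputed matrix, low-dimensional factor, per-layer log."""

    high_dim: ExpressionMatrix
    low_dim: np.ndarray
    per_layer_rms: list[float]
    schedule: LayerSchedule
    config: ScirtConfig = field(default_factory=ScirtConfig)
    layer_matrices: list[np.ndarray] = field(default_factory=list)


def build_schedule(y: int, nc: int, shrink: float = 0.9) -> LayerSchedule:
    """Compute the layer schedule for y cells and nc expected types.

    mean_number = floor(log2(y/nc)); times = (2, 4, ..., 2^mean_number);
    eec = floor(y/nc * shrink). Layer l uses p = 1/times[l] while
    times[l] <= eec; the top layer (and any layer whose neighborhood
    already exceeds eec) uses the flat p = nc/y.
    """
    if nc < 1:
        raise ValidationError("nc must be >= 1")
    if y <= nc:
        raise ValidationError(
            f"cannot build layers for y={y} cells and nc={nc} clusters: need y > nc"
        )
    mean_number = int(math.floor(math.log2(y / nc)))
    if mean_number < 1:
        raise ValidationError(
            f"y/nc = {y / nc:.3f} < 2 leaves no room for layering"
        )
    times = tuple(2 ** l for l in range(1, mean_number + 1))
    eec = int(math.floor(y / nc * shrink))
    flat_p = layer_parameter(nc, shrink=1.0, y=y)  # nc / y
    p_schedule = []
    for l, t in enumerate(times):
        top = l == mean_number - 1
        p_schedule.append(flat_p if top or t > eec else 1.0 / t)
    return LayerSchedule(
        mean_number=mean_number,
        times=times,
        eec=eec,
        p_schedule=tuple(p_schedule),
        shrink=shrink,
    )


def run_scirt(
    matrix: ExpressionMatrix, nc: int, config: ScirtConfig | None = None
) -> ScirtResult:
    """Run the full multi-layer imputation pipeline.

    Per layer: (a) recompute the ensemble consensus on the current matrix,
    (b) impute every cell with that layer's geometric parameter, (c)
    replace the matrix by its rank-k NMF reconstruction and log the RMS
    residual. A final factorization of the last reconstruction gives
    ``high_dim`` (Z @ H, same shape as the input) and ``low_dim``
    (Z, cells x k). Fully deterministic under ``config.seed``.
    """
    if config is None:
        config = ScirtConfig()
    schedule = build_schedule(matrix.n_cells, nc, shrink=config.shrink)
    k = config.k if config.k is not None else nc
    rng = np.random.default_rng(config.seed)

    current = matrix
    consensus = None
    per_layer_rms: list[float] = []
    layer_matrices: list[np.ndarray] = []
    for layer_index, p in enumerate(schedule.p_schedule):
        if consensus is None or not config.freeze_ranks:
            consensus = consensus_matrix(current, config.metrics, config.metric_weights)
        imputed = impute_layer(
            current, consensus, p=p, re=config.re, window=config.window, rng=rng
        )
        nmf_seed = int(rng.integers(2 ** 31))
        factors = nmf_factorize(
            imputed.values,
            NmfConfig(
                k=k,
                max_iter=config.nmf_max_iter,
                tol=config.nmf_tol,
                noise_model=config.noise_model,  # type: ignore[arg-type]
                seed=nmf_seed,
            ),
        )
        recon = factors.reconstruction()
        if not np.all(np.isfinite(recon)):
            raise FloatingPointError(
                f"non-finite values after NMF reconstruction at layer {layer_index + 1}"
            )
        per_layer_rms.append(float(np.sqrt(np.mean((imputed.values - recon) ** 2))))
        current = ExpressionMatrix(recon, list(matrix.cell_ids), list(matrix.gene_ids))
        if config.keep_layers:
            layer_matrices.append(recon.copy())

    final_seed = int(rng.integers(2 ** 31))
    final = nmf_factorize(
        current.values,
        NmfConfig(
            k=k,
            max_iter=config.nmf_max_iter,
            tol=config.nmf_tol,
            noise_model=config.noise_model,  # type: ignore[arg-type]
            seed=final_seed,
        ),
    )
    high_dim = ExpressionMatrix(
        final.reconstruction(), list(matrix.cell_ids), list(matrix.gene_ids)
    )
    return ScirtResult(
        high_dim=high_dim,
        low_dim=final.Z.copy(),
        per_layer_rms=per_layer_rms,
        schedule=schedule,
        config=config,
        layer_matrices=layer_matrices,
    )
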