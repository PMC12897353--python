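"""Non-negative matrix factorization with Lee-Seung multiplicative updates.

A ~= Z @ H with Z (u x k) and H (k x v) elementwise non-negative, fit by
multiplicative updates under either a Gaussian noise model (squared
Frobenius objective) or a Poisson noise model (generalized Kullback-Leibler
objective). Both update families are monotone: the matching objective never
increases across a paired (Z, H) update.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from scirt.expression_io import ValidationError

logger = logging.getLogger(__name__)

EPSILON = 1e-12
NoiseModel = Literal["gaussian", "poisson"]


@dataclass
class NmfConfig:
    """Factorization settings: rank, stopping rule, noise model, seed."""

    k: int = 2
    max_iter: int = 200
    tol: float = 1e-4
    noise_model: NoiseModel = "gaussian"
    seed: int = 0
    epsilon: float = EPSILON

    def validate(self) -> None:
        if self.k < 1:
            raise ValidationError("rank k must be >= 1")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValidationError("tol must be positive")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValidationError(f"unknown noise model {self.noise_model!r}")


@dataclass
class FactorPair:
    """Fitted non-negative factors with the per-iteration objective trace."""

    Z: np.ndarray
    H: np.ndarray
    k: int
    objective_trace: list[float] = field(default_factory=list)
    noise_model: NoiseModel = "gaussian"

    def reconstruction(self) -> np.ndarray:
        return self.Z @ self.H


def objective_euclidean(A: np.ndarray, Z: np.ndarray, H: np.ndarray) -> float:
    """Squared Frobenius residual sum_{u,v} (A_uv - (ZH)_uv)^2."""
    R = np.asarray(A, dtype=float) - Z @ H
    return float(np.sum(R * R))


def objective_kl(
    A: np.ndarray, Z: np.ndarray, H: np.ndarray, epsilon: float = EPSILON
) -> float:
    """Generalized KL divergence D(A || ZH) = sum A log(A/ZH) - A + ZH.

    Uses the 0*log(0) = 0 convention and epsilon-guards the ratio's
    denominator, so zero entries in A or the reconstruction stay finite.
    """
    A = np.asarray(A, dtype=float)
    ZH = Z @ H
    ratio_term = np.zeros_like(A)
    pos = A > 0
    ratio_term[pos] = A[pos] * np.log(A[pos] / np.maximum(ZH[pos], epsilon))
    return float(np.sum(ratio_term - A + ZH))


def update_gaussian(
    A: np.ndarray, Z: np.ndarray, H: np.ndarray, epsilon: float = EPSILON
) -> tuple[np.ndarray, np.ndarray]:
    """One paired multiplicative update under the Gaussian (Frobenius) model.

    Z <- Z * (A H^T) / (Z H H^T), then H <- H * (Z^T A) / (Z^T Z H), using
    the already-updated Z so the paired step is monotone.
    """
    A = np.asarray(A, dtype=float)
    Z = Z * (A @ H.T) / (Z @ H @ H.T + epsilon)
    H = H * (Z.T @ A) / (Z.T @ Z @ H + epsilon)
    return Z, H


def update_poisson(
    A: np.ndarray, Z: np.ndarray, H: np.ndarray, epsilon: float = EPSILON
) -> tuple[np.ndarray, np.ndarray]:
    """One paired multiplicative update under the Poisson (KL) model.

    Z_uk <- Z_uk * (sum_v H_kv A_uv/(ZH)_uv) / (sum_v H_kv), then the
    symmetric rule for H with the updated Z.
    """
    A = np.asarray(A, dtype=float)
    ratio = A / (Z @ H + epsilon)
    Z = Z * (ratio @ H.T) / (H.sum(axis=1)[None, :] + epsilon)
    ratio = A / (Z @ H + epsilon)
    H = H * (Z.T @ ratio) / (Z.sum(axis=0)[:, None] + epsilon)
    return Z, H


def nmf_factorize(A: np.ndarray, config: NmfConfig | None = None, **kwargs) -> FactorPair:
    """Fit A ~= Z H by iterating the configured multiplicative update.

    Initialization is seeded uniform(0, 1) scaled by sqrt(mean(A)/k), which
    puts the initial reconstruction on the scale of A. Iteration stops when
    the relative objective change drops below ``tol`` or at ``max_iter``.
    An all-zero A short-circuits to zero factors with objective 0.
    """
    if config is None:
        config = NmfConfig(**kwargs)
    elif kwargs:
        raise TypeError("pass either a config or keyword settings, not both")
    config.validate()
    A = np.asarray(A, dtype=float)
    if A.ndim != 2:
        raise ValidationError("A must be 2-D")
    if np.any(A < 0):
        raise ValidationError("A must be non-negative")
    u, v = A.shape
    k = config.k
    if k > min(u, v):
        logger.warning("rank k=%d exceeds min(u, v)=%d", k, min(u, v))

    if not np.any(A):
        return FactorPair(
            Z=np.zeros((u, k)),
            H=np.zeros((k, v)),
            k=k,
            objective_trace=[0.0],
            noise_model=config.noise_model,
        )

    rng = np.random.default_rng(config.seed)
    scale = np.sqrt(A.mean() / k)
    Z = scale * rng.uniform(size=(u, k))
    H = scale * rng.uniform(size=(k, v))
    np.maximum(Z, config.epsilon, out=Z)
    np.maximum(H, config.epsilon, out=H)

    if config.noise_model == "gaussian":
        objective, update = objective_euclidean, update_gaussian
    else:
        objective, update = objective_kl, update_poisson

    trace = [objective(A, Z, H)]
    for _ in range(config.max_iter):
        Z, H = update(A, Z, H, epsilon=config.epsilon)
        np.maximum(Z, config.epsilon, out=Z)
        np.maximum(H, config.epsilon, out=H)
        trace.append(objective(A, Z, H))
        prev, curr = trace[-2], trace[-1]
        if abs(prev - curr) <= config.tol * max(abs(prev), config.epsilon):
            break
    return FactorPair(Z=Z, H=H, k=k, objective_trace=trace, noise_model=config.noise_model)
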