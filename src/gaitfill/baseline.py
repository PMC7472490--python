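"""Iterative-PCA gap imputation, the comparison baseline.

A conventional EM-style principal-subspace completion: initialise missing
entries by per-channel linear interpolation, then alternate between fitting a
rank-k principal subspace to the current completed matrix and re-projecting,
restoring the observed entries after every pass.  It stands in for the
PCA-family reconstruction algorithms used in the gait literature; it is a
documented conventional implementation, so comparisons against it are
directional (the convex models beat *this* baseline), not reproductions of
published per-dataset numbers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .admm import interpolate_missing
from .trajectory import ObservationMask, RecoveryResult, TrajectoryMatrix

__all__ = ["PCABaselineConfig", "pca_impute"]

logger = logging.getLogger(__name__)


@dataclass
class PCABaselineConfig:
    """Baseline parameters: fix ``n_components`` directly, or let
    ``variance_threshold`` pick the smallest k explaining that fraction of
    variance (exactly one of the two may be set; defaults to a 0.95
    variance threshold)."""

    n_components: int | None = None
    variance_threshold: float | None = None
    max_iter: int = 200
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.n_components is not None and self.variance_threshold is not None:
            raise ValueError("set exactly one of n_components / variance_threshold")
        if self.n_components is None and self.variance_threshold is None:
            self.variance_threshold = 0.95
        if self.n_components is not None and self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.variance_threshold is not None and not (0 < self.variance_threshold <= 1):
            raise ValueError("variance_threshold must be in (0, 1]")
        if self.max_iter < 1 or self.tol <= 0:
            raise ValueError("max_iter must be >= 1 and tol positive")


def _fix_signs(U: np.ndarray, Vt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # deterministic orientation: largest-|loading| entry of each component
    # positive; the paired flip of U keeps the product unchanged
    signs = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
    signs[signs == 0] = 1.0
    return U * signs[None, :], Vt * signs[:, None]


def pca_impute(
    Y: TrajectoryMatrix,
    mask: ObservationMask | None = None,
    cfg: PCABaselineConfig | None = None,
) -> RecoveryResult:
    """Fill gaps by iterative principal-subspace re-projection.

    The component count is chosen once, from the interpolation-initialised
    matrix.  Observed entries of the output equal the input bit-exactly; the
    per-iteration relative change of the imputed block is recorded in
    ``change_history``.
    """
    cfg = cfg or PCABaselineConfig()
    if mask is None:
        mask = ObservationMask.from_values(Y.values)
    mask.check_compatible(Y)
    mask.check_recoverable(Y.marker_names)
    obs = mask.observed

    X = interpolate_missing(Y.values, obs)
    missing = ~obs

    mu0 = X.mean(axis=0)
    s0 = np.linalg.svd(X - mu0, compute_uv=False)
    if cfg.n_components is not None:
        k = min(cfg.n_components, len(s0))
    else:
        var = s0**2
        total = var.sum()
        if total == 0:
            k = 1
        else:
            k = int(np.searchsorted(np.cumsum(var) / total, cfg.variance_threshold) + 1)
            k = min(k, len(s0))

    changes: list[float] = []
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        mu = X.mean(axis=0)
        U, s, Vt = np.linalg.svd(X - mu, full_matrices=False)
        U, Vt = _fix_signs(U, Vt)
        low_rank = (U[:, :k] * s[:k]) @ Vt[:k] + mu
        X_new = X.copy()
        X_new[missing] = low_rank[missing]
        denom = max(1.0, float(np.linalg.norm(X[missing])))
        change = float(np.linalg.norm(X_new[missing] - X[missing]) / denom)
        changes.append(change)
        X = X_new
        if change < cfg.tol:
            converged = True
            break

    if not converged:
        logger.warning("PCA imputation did not converge in %d iterations", cfg.max_iter)

    completed = TrajectoryMatrix(X, Y.frame_rate, list(Y.marker_names))
    completed.values[obs] = Y.values[obs]
    return RecoveryResult(
        completed=completed,
        iterations=it,
        converged=converged,
        change_history=changes,
    )
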