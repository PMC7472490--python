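"""Core data containers for marker-trajectory completion.

A capture session with ``m`` markers sampled over ``n`` frames is stored as an
``n x 3m`` real matrix: each column is one coordinate channel's time series, and
marker ``k`` owns the three consecutive columns ``(3k, 3k+1, 3k+2)`` holding its
x, y, z coordinates in millimetres.  Time running down the rows is what makes
the frequency-domain group prior meaningful: after a DFT along axis 0, each row
of the spectrum is one frequency bin shared by every channel, so "all channels
use the same frequencies" is literal row-sparsity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "TrajectoryMatrix",
    "ObservationMask",
    "SpectralWeights",
    "SolverConfig",
    "ADMMState",
    "RecoveryResult",
    "UnrecoverableChannelError",
    "mask_from_nan",
    "select_markers",
]


class UnrecoverableChannelError(ValueError):
    """A coordinate channel has no observed samples at all."""


@dataclass
class TrajectoryMatrix:
    """Marker trajectories: ``n_frames x n_channels`` millimetre matrix.

    Parameters
    ----------
    values : ndarray of shape (n_frames, 3 * n_markers)
        Coordinate time series; NaN marks a missing sample.
    frame_rate : float
        Sampling rate in Hz.
    marker_names : sequence of str
        One label per marker; channel ``3k + j`` is coordinate ``j`` (x, y, z)
        of marker ``k``.
    """

    values: np.ndarray
    frame_rate: float
    marker_names: Sequence[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.marker_names = list(self.marker_names)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array (frames x channels)")
        if self.values.shape[0] < 2:
            raise ValueError("need at least 2 frames for a meaningful spectrum")
        if self.values.shape[1] != 3 * len(self.marker_names):
            raise ValueError(
                f"{self.values.shape[1]} channels do not match "
                f"{len(self.marker_names)} markers (expected 3 per marker)"
            )
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def n_markers(self) -> int:
        return len(self.marker_names)

    def marker_channels(self, k: int) -> slice:
        """Column slice owning marker ``k``'s x, y, z channels."""
        return slice(3 * k, 3 * k + 3)

    def copy(self) -> "TrajectoryMatrix":
        return TrajectoryMatrix(self.values.copy(), self.frame_rate, list(self.marker_names))


def mask_from_nan(values: np.ndarray) -> np.ndarray:
    """Boolean observed-mask from NaN positions (True = observed)."""
    return np.isfinite(np.asarray(values, dtype=float))


@dataclass
class ObservationMask:
    """Boolean matrix marking observed entries (True = observed)."""

    observed: np.ndarray

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=bool)
        if self.observed.ndim != 2:
            raise ValueError("observed must be 2-D")

    @classmethod
    def from_values(cls, values: np.ndarray) -> "ObservationMask":
        return cls(mask_from_nan(values))

    def check_compatible(self, traj: TrajectoryMatrix) -> None:
        if self.observed.shape != traj.values.shape:
            raise ValueError(
                f"mask shape {self.observed.shape} does not match "
                f"trajectory shape {traj.values.shape}"
            )

    def check_recoverable(self, marker_names: Sequence[str] | None = None) -> None:
        """Raise if any channel has zero observed entries."""
        counts = self.observed.sum(axis=0)
        bad = np.flatnonzero(counts == 0)
        if bad.size:
            j = int(bad[0])
            name = ""
            if marker_names is not None:
                coord = "xyz"[j % 3]
                name = f" (marker {marker_names[j // 3]!r}, coordinate {coord})"
            raise UnrecoverableChannelError(
                f"channel {j}{name} has no observed samples and cannot be recovered"
            )

    @property
    def missing_fraction(self) -> float:
        return 1.0 - float(self.observed.mean())


@dataclass
class SpectralWeights:
    """Per-frequency-bin penalty weights.

    Bins whose folded index ``min(i, n - i)`` exceeds ``threshold_bin`` get
    ``high_weight``; the pass band gets ``low_weight``.  Folding keeps the
    penalty conjugate-symmetric, so penalised real signals stay real.
    """

    n_frames: int
    threshold_bin: int = 100
    high_weight: float = 100.0
    low_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.high_weight < 0 or self.low_weight < 0:
            raise ValueError("weights must be non-negative")
        if self.threshold_bin < 0:
            raise ValueError("threshold_bin must be non-negative")

    @property
    def weights(self) -> np.ndarray:
        i = np.arange(self.n_frames)
        folded = np.minimum(i, self.n_frames - i)
        return np.where(folded > self.threshold_bin, self.high_weight, self.low_weight).astype(float)

    @classmethod
    def from_cutoff_hz(
        cls,
        cutoff_hz: float,
        n_frames: int,
        frame_rate: float,
        high_weight: float = 100.0,
        low_weight: float = 1.0,
    ) -> "SpectralWeights":
        """Convenience: convert a Hz cutoff to a bin index (bin = f * n / rate)."""
        threshold_bin = int(round(cutoff_hz * n_frames / frame_rate))
        return cls(n_frames, threshold_bin, high_weight, low_weight)


@dataclass
class SolverConfig:
    """Hyper-parameters of the splitting solver.

    ``lam`` trades the nuclear norm against the spectral sparsity penalty
    (scale-dependent: about 1e4-1e5 for millimetre-scale gait data);
    ``mu_a``/``mu_b`` are the augmented-Lagrangian weights of the low-rank and
    spectral couplings; ``sparsity_mode`` selects the entrywise l1 penalty
    (S-LR) or the row-wise l1,2 group penalty (GS-LR).
    """

    lam: float = 1e4
    mu_a: float = 1.0
    mu_b: float = 1.0
    sparsity_mode: str = "entrywise"
    max_iter: int = 500
    tol: float = 1e-6
    window_frames: int | None = None

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be non-negative")
        if self.mu_a <= 0 or self.mu_b <= 0:
            raise ValueError("mu_a and mu_b must be positive")
        if self.sparsity_mode not in ("entrywise", "group"):
            raise ValueError("sparsity_mode must be 'entrywise' or 'group'")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.window_frames is not None and self.window_frames < 2:
            raise ValueError("window_frames must be >= 2 when set")

    def replace(self, **kw) -> "SolverConfig":
        return replace(self, **kw)


@dataclass
class ADMMState:
    """Iterates of the splitting: estimate X, auxiliaries Q (low-rank) and
    R (spectrum), multipliers A (for Q = X) and B (for R = FX)."""

    X: np.ndarray
    Q: np.ndarray
    R: np.ndarray
    A: np.ndarray
    B: np.ndarray

    def __post_init__(self) -> None:
        shape = self.X.shape
        for name in ("Q", "R", "A", "B"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} shape {getattr(self, name).shape} != X shape {shape}")
        if np.iscomplexobj(self.A):
            raise ValueError("multiplier A must be real")


@dataclass
class RecoveryResult:
    """Completed trajectories plus solver diagnostics."""

    completed: TrajectoryMatrix
    iterations: int
    converged: bool
    residual_history: list = field(default_factory=list)
    objective_history: list = field(default_factory=list)
    change_history: list = field(default_factory=list)


def select_markers(
    traj: TrajectoryMatrix, marker_subset: Sequence[str]
) -> TrajectoryMatrix:
    """Restrict a trajectory matrix to a subset of markers (column triples)."""
    name_to_idx = {name: k for k, name in enumerate(traj.marker_names)}
    missing = [m for m in marker_subset if m not in name_to_idx]
    if missing:
        raise ValueError(f"unknown markers: {missing}")
    cols: list[int] = []
    for m in marker_subset:
        k = name_to_idx[m]
        cols.extend(range(3 * k, 3 * k + 3))
    return TrajectoryMatrix(traj.values[:, cols], traj.frame_rate, list(marker_subset))
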