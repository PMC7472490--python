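"""scikit-learn-style imputers wrapping the completion solvers.

The completion problem is transductive — there is no model carried from one
capture to another — so, as with matrix-completion imputers generally, the
work happens in :meth:`transform` (and :meth:`fit_transform`): ``fit``
validates the input and records its shape, ``transform`` solves the
completion for the matrix it is given.  Inputs are plain ``(n_frames,
n_channels)`` arrays with NaN marking missing samples, ``n_channels`` a
multiple of three (x, y, z per marker); solver diagnostics are exposed as
fitted attributes (``n_iter_``, ``converged_``, ...).  The estimators are
clonable and compose with sklearn pipelines.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .admm import recover
from .baseline import PCABaselineConfig, pca_impute
from .trajectory import ObservationMask, SolverConfig, SpectralWeights, TrajectoryMatrix

__all__ = ["SparseLowRankImputer", "GroupSparseLowRankImputer", "PCAImputer"]


def _as_trajectory(X: np.ndarray, frame_rate: float) -> TrajectoryMatrix:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (n_frames, n_channels)")
    if X.shape[1] % 3 != 0:
        raise ValueError("n_channels must be a multiple of 3 (x, y, z per marker)")
    names = [f"M{k:02d}" for k in range(X.shape[1] // 3)]
    return TrajectoryMatrix(X, frame_rate, names)


class SparseLowRankImputer(TransformerMixin, BaseEstimator):
    """Fill trajectory gaps by nuclear-norm + weighted spectral-l1 completion.

    Solves ``min ||X||_* + lam ||W F X||_1 s.t. observed entries match`` via
    ADMM.  With ``sparsity="group"`` the penalty becomes the row-wise l1,2
    norm, coupling all channels' spectra (the group-sparse variant).

    Parameters
    ----------
    lam : float, default 1e4
        Sparsity/low-rank trade-off; scale-dependent (1e4-1e5 suits
        millimetre-scale gait data).
    mu_a, mu_b : float, default 1.0
        Augmented-Lagrangian weights of the low-rank and spectral couplings.
    sparsity : {"entrywise", "group"}
        Entrywise l1 (S-LR) or row-group l1,2 (GS-LR) spectral penalty.
    theta_f : int, default 100
        Frequency-bin cutoff: folded bins above it are penalised by
        ``high_weight``, others by ``low_weight``.
    max_iter, tol : solver stopping rule (both relative primal residuals
        below ``tol``).
    window_frames : int or None
        Optional non-overlapping window length; windows are solved
        independently.
    frame_rate : float, default 240.0
        Metadata only (carried through to outputs).

    Attributes
    ----------
    n_iter_ : int
        ADMM iterations of the last transform.
    converged_ : bool
    residual_history_ : list of (float, float)
        Relative primal residuals per iteration.
    objective_history_ : list of float
    """

    def __init__(
        self,
        lam: float = 1e4,
        mu_a: float = 1.0,
        mu_b: float = 1.0,
        sparsity: str = "entrywise",
        theta_f: int = 100,
        high_weight: float = 100.0,
        low_weight: float = 1.0,
        max_iter: int = 500,
        tol: float = 1e-6,
        window_frames: int | None = None,
        frame_rate: float = 240.0,
    ):
        self.lam = lam
        self.mu_a = mu_a
        self.mu_b = mu_b
        self.sparsity = sparsity
        self.theta_f = theta_f
        self.high_weight = high_weight
        self.low_weight = low_weight
        self.max_iter = max_iter
        self.tol = tol
        self.window_frames = window_frames
        self.frame_rate = frame_rate

    def _config(self) -> SolverConfig:
        return SolverConfig(
            lam=self.lam,
            mu_a=self.mu_a,
            mu_b=self.mu_b,
            sparsity_mode=self.sparsity,
            max_iter=self.max_iter,
            tol=self.tol,
            window_frames=self.window_frames,
        )

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        _as_trajectory(X, self.frame_rate)  # validation
        self._config()
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        """Return a completed copy of ``X`` (NaNs filled, observed entries
        untouched)."""
        if not hasattr(self, "n_features_in_"):
            self.fit(X)
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} channels; imputer was fitted with {self.n_features_in_}"
            )
        traj = _as_trajectory(X, self.frame_rate)
        weights = SpectralWeights(
            traj.n_frames, self.theta_f, self.high_weight, self.low_weight
        )
        result = recover(traj, ObservationMask.from_values(X), weights, self._config())
        self.n_iter_ = result.iterations
        self.converged_ = result.converged
        self.residual_history_ = result.residual_history
        self.objective_history_ = result.objective_history
        return result.completed.values


class GroupSparseLowRankImputer(SparseLowRankImputer):
    """The group-sparse variant: row-wise l1,2 penalty on the spectrum, so
    all coordinate channels are pushed toward a shared frequency support."""

    def __init__(
        self,
        lam: float = 1e4,
        mu_a: float = 1.0,
        mu_b: float = 1.0,
        theta_f: int = 100,
        high_weight: float = 100.0,
        low_weight: float = 1.0,
        max_iter: int = 500,
        tol: float = 1e-6,
        window_frames: int | None = None,
        frame_rate: float = 240.0,
    ):
        super().__init__(
            lam=lam,
            mu_a=mu_a,
            mu_b=mu_b,
            sparsity="group",
            theta_f=theta_f,
            high_weight=high_weight,
            low_weight=low_weight,
            max_iter=max_iter,
            tol=tol,
            window_frames=window_frames,
            frame_rate=frame_rate,
        )


class PCAImputer(TransformerMixin, BaseEstimator):
    """Iterative principal-subspace gap imputation (the PCA baseline).

    Parameters mirror :class:`gaitfill.baseline.PCABaselineConfig`; exactly
    one of ``n_components`` / ``variance_threshold`` may be set (default:
    variance threshold 0.95).
    """

    def __init__(
        self,
        n_components: int | None = None,
        variance_threshold: float | None = None,
        max_iter: int = 200,
        tol: float = 1e-6,
        frame_rate: float = 240.0,
    ):
        self.n_components = n_components
        self.variance_threshold = variance_threshold
        self.max_iter = max_iter
        self.tol = tol
        self.frame_rate = frame_rate

    def _config(self) -> PCABaselineConfig:
        return PCABaselineConfig(
            n_components=self.n_components,
            variance_threshold=self.variance_threshold,
            max_iter=self.max_iter,
            tol=self.tol,
        )

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        _as_trajectory(X, self.frame_rate)
        self._config()
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        if not hasattr(self, "n_features_in_"):
            self.fit(X)
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} channels; imputer was fitted with {self.n_features_in_}"
            )
        traj = _as_trajectory(X, self.frame_rate)
        result = pca_impute(traj, ObservationMask.from_values(X), self._config())
        self.n_iter_ = result.iterations
        self.converged_ = result.converged
        self.change_history_ = result.change_history
        return result.completed.values
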