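"""Proximal operators and the unitary column-wise DFT.

The transform is unitary (``norm="ortho"``), so its adjoint is its inverse,
Parseval holds exactly, and the singular values of ``F X`` equal those of
``X`` — the property that lets a single nuclear-norm prior constrain the rank
in both the time and frequency domains.
"""

from __future__ import annotations

import numpy as np
from scipy import fft as _fft

__all__ = ["unitary_dft", "unitary_idft", "soft_threshold", "svt", "group_shrink"]


def _check_finite(M: np.ndarray, name: str = "input") -> np.ndarray:
    M = np.asarray(M)
    if not np.all(np.isfinite(M.real)) or (np.iscomplexobj(M) and not np.all(np.isfinite(M.imag))):
        raise ValueError(f"{name} contains non-finite entries")
    return M


def unitary_dft(M: np.ndarray) -> np.ndarray:
    """Unitary DFT of each column (time runs down the rows).

    Row ``i`` of the output is frequency bin ``i``; ``||F M||_F == ||M||_F``.
    """
    M = _check_finite(M)
    return _fft.fft(M, axis=0, norm="ortho")


def unitary_idft(M: np.ndarray) -> np.ndarray:
    """Inverse of :func:`unitary_dft` (complex output; take ``.real`` for
    spectra known to be conjugate-symmetric)."""
    M = _check_finite(M)
    return _fft.ifft(M, axis=0, norm="ortho")


def soft_threshold(c, gamma):
    """Magnitude shrinkage ``max(|c| - gamma, 0) * c / |c|`` (prox of the
    weighted l1 norm; phase-preserving, so it covers complex spectra and
    reduces to ``sign(c) * max(|c| - gamma, 0)`` on reals).

    ``gamma`` may be a scalar or an array broadcastable against ``c``.
    """
    c = np.asarray(c)
    gamma = np.asarray(gamma, dtype=float)
    if np.any(gamma < 0):
        raise ValueError("gamma must be non-negative")
    mag = np.abs(c)
    shrunk = np.maximum(mag - gamma, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(mag > 0, shrunk * np.divide(c, np.where(mag > 0, mag, 1.0)), 0.0)
    if out.ndim == 0:
        return out[()]
    return out


def svt(M: np.ndarray, gamma: float) -> np.ndarray:
    """Singular-value thresholding: prox of ``gamma * ||.||_*`` at ``M``.

    Returns ``U max(S - gamma, 0) V^T`` for the SVD ``M = U S V^T``.
    """
    M = _check_finite(M, "matrix")
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    s = np.maximum(s - gamma, 0.0)
    return (U * s) @ Vt


def group_shrink(C: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    """Row-wise group shrinkage: row ``i`` becomes
    ``max(||c_i||_2 - gamma_i, 0) * c_i / ||c_i||_2`` (zero rows stay zero).

    Prox of the weighted l1,2 norm; the whole row is scaled or zeroed jointly,
    which is what enforces a shared frequency support across channels.
    """
    C = np.asarray(C)
    gamma = np.broadcast_to(np.asarray(gamma, dtype=float), (C.shape[0],))
    if np.any(gamma < 0):
        raise ValueError("gamma must be non-negative")
    norms = np.linalg.norm(C, axis=1)
    scale = np.zeros_like(norms)
    nz = norms > 0
    scale[nz] = np.maximum(norms[nz] - gamma[nz], 0.0) / norms[nz]
    return C * scale[:, None]
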