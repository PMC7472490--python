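"""Independent numerical oracles for the solver's closed-form sub-steps.

Every oracle minimises the relevant convex objective directly with a generic
scipy optimiser (derivative-free Powell for small separable problems, L-BFGS
on a tightly smoothed surrogate for spectral functions), sharing no code with
the closed-form implementations they check.
"""

from __future__ import annotations

import numpy as np
from scipy import fft as sfft
from scipy.optimize import minimize

_POWELL_OPTS = {"xtol": 1e-12, "ftol": 1e-14, "maxiter": 100000, "maxfev": 100000}


def prox_nuclear_numeric(M: np.ndarray, gamma: float, eps: float = 1e-6) -> np.ndarray:
    """argmin_Q ||Q||_* + 1/(2 gamma) ||Q - M||_F^2 by smoothed L-BFGS.

    The nuclear norm is smoothed as sum sqrt(s_i^2 + eps^2); strong convexity
    1/gamma bounds the induced argmin bias well below 1e-4 at eps=1e-6.
    """

    def fg(q):
        Q = q.reshape(M.shape)
        U, s, Vt = np.linalg.svd(Q, full_matrices=False)
        f = np.sum(np.sqrt(s**2 + eps**2)) + np.sum((Q - M) ** 2) / (2 * gamma)
        G = (U * (s / np.sqrt(s**2 + eps**2))) @ Vt + (Q - M) / gamma
        return f, G.ravel()

    x = M.ravel()
    for _ in range(3):
        x = minimize(
            fg, x, jac=True, method="L-BFGS-B",
            options={"maxiter": 20000, "ftol": 1e-18, "gtol": 1e-14, "maxcor": 30},
        ).x
    return x.reshape(M.shape)


def prox_l1_complex_numeric(c: complex, gamma: float) -> complex:
    """argmin_r gamma |r| + 1/2 |r - c|^2 over complex r (2-D Powell)."""

    def f(v):
        return gamma * np.hypot(v[0], v[1]) + 0.5 * ((v[0] - c.real) ** 2 + (v[1] - c.imag) ** 2)

    x = minimize(f, [c.real, c.imag], method="Powell", options=_POWELL_OPTS).x
    return complex(x[0], x[1])


def prox_group_row_numeric(c: np.ndarray, gamma: float) -> np.ndarray:
    """argmin_r gamma ||r||_2 + 1/2 ||r - c||_2^2 over a complex row (Powell)."""
    m = c.size

    def f(v):
        r = v[:m] + 1j * v[m:]
        return gamma * np.linalg.norm(r) + 0.5 * np.sum(np.abs(r - c) ** 2)

    x = minimize(f, np.concatenate([c.real, c.imag]), method="Powell", options=_POWELL_OPTS).x
    return x[:m] + 1j * x[m:]


def x_subproblem_numeric(
    Y: np.ndarray,
    observed: np.ndarray,
    T_lowrank: np.ndarray,
    T_spectral: np.ndarray,
    mu_a: float,
    mu_b: float,
) -> np.ndarray:
    """argmin_X mu_a/2 ||X - T_lowrank||^2 + mu_b/2 ||F X - T_spectral||^2
    subject to X = Y at observed entries, by BFGS over the free entries."""
    free = ~observed

    def build(v):
        X = Y.copy()
        X[free] = v
        return X

    def f(v):
        X = build(v)
        FX = sfft.fft(X, axis=0, norm="ortho")
        return 0.5 * mu_a * np.sum((X - T_lowrank) ** 2) + 0.5 * mu_b * np.sum(
            np.abs(FX - T_spectral) ** 2
        )

    x0 = np.zeros(free.sum())
    x = minimize(f, x0, method="BFGS", options={"maxiter": 20000, "gtol": 1e-12}).x
    return build(x)


def slr_objective_exact(X: np.ndarray, weights: np.ndarray, lam: float) -> float:
    """||X||_* + lam ||W F X||_1 (entrywise), evaluated exactly."""
    nuc = float(np.linalg.svd(X, compute_uv=False).sum())
    FX = sfft.fft(X, axis=0, norm="ortho")
    return nuc + lam * float(np.sum(weights[:, None] * np.abs(FX)))


def slr_minimize_numeric(
    Y: np.ndarray,
    observed: np.ndarray,
    weights: np.ndarray,
    lam: float,
    x0: np.ndarray,
    eps: float = 1e-7,
) -> np.ndarray:
    """Minimise the full S-LR objective over the free entries with smoothed
    L-BFGS (generic convex solver stand-in for tiny instances)."""
    free = ~observed

    def build(v):
        X = Y.copy()
        X[free] = v
        return X

    def fg(v):
        X = build(v)
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        f = np.sum(np.sqrt(s**2 + eps**2))
        G = (U * (s / np.sqrt(s**2 + eps**2))) @ Vt
        FX = sfft.fft(X, axis=0, norm="ortho")
        a = np.sqrt(np.abs(FX) ** 2 + eps**2)
        f += lam * np.sum(weights[:, None] * a)
        G = G + sfft.ifft(lam * weights[:, None] * FX / a, axis=0, norm="ortho").real
        return f, G[free]

    x = x0[free]
    for _ in range(4):
        x = minimize(
            fg, x, jac=True, method="L-BFGS-B",
            options={"maxiter": 50000, "ftol": 1e-18, "gtol": 1e-14, "maxcor": 40},
        ).x
    return build(x)
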