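"""Each splitting sub-step against its closed form and numerical oracle."""

import numpy as np
import pytest

from gaitfill.admm import update_multipliers, update_q, update_r, update_x
from gaitfill.operators import svt, unitary_dft, unitary_idft
from gaitfill.trajectory import ADMMState, SolverConfig, SpectralWeights

from _oracles import (
    prox_l1_complex_numeric,
    prox_group_row_numeric,
    x_subproblem_numeric,
)


def make_state(rng, n=6, m=4):
    X = rng.standard_normal((n, m))
    return ADMMState(
        X=X,
        Q=rng.standard_normal((n, m)),
        R=rng.standard_normal((n, m)) + 1j * rng.standard_normal((n, m)),
        A=rng.standard_normal((n, m)),
        B=rng.standard_normal((n, m)) + 1j * rng.standard_normal((n, m)),
    )


class TestUpdateX:
    def test_fully_observed_returns_input(self, rng):
        state = make_state(rng)
        Y = rng.standard_normal((6, 4))
        out = update_x(state, Y, np.ones((6, 4), bool), SolverConfig())
        np.testing.assert_array_equal(out, Y)

    def test_agreeing_targets_pass_through(self, rng):
        # when Q + A and the inverse-transformed R + B coincide, the weighted
        # average is that common value regardless of mu
        n, m = 8, 3
        M = rng.standard_normal((n, m))
        state = make_state(rng, n, m)
        state.Q = M - state.A
        state.R = unitary_dft(M) - state.B
        Y = rng.standard_normal((n, m))
        observed = rng.random((n, m)) < 0.5
        out = update_x(state, Y, observed, SolverConfig(mu_a=0.3, mu_b=2.1))
        np.testing.assert_allclose(out[~observed], M[~observed], atol=1e-12)
        np.testing.assert_array_equal(out[observed], Y[observed])

    def test_matches_constrained_least_squares_oracle(self, rng):
        n, m = 3, 3
        state = make_state(rng, n, m)
        Y = rng.standard_normal((n, m))
        observed = np.array([[1, 0, 1], [0, 1, 0], [1, 1, 0]], bool)
        cfg = SolverConfig(mu_a=0.7, mu_b=1.9)
        out = update_x(state, Y, observed, cfg)
        expected = x_subproblem_numeric(
            Y, observed, state.Q + state.A, state.R + state.B, cfg.mu_a, cfg.mu_b
        )
        np.testing.assert_allclose(out, expected, atol=1e-5)


class TestUpdateQ:
    def test_zero_input_gives_zero(self, rng):
        state = make_state(rng)
        state.A = state.X.copy()
        np.testing.assert_allclose(update_q(state, SolverConfig()), 0.0, atol=1e-12)

    def test_is_svt_of_x_minus_a(self, rng):
        state = make_state(rng)
        cfg = SolverConfig(mu_a=0.5)
        np.testing.assert_allclose(
            update_q(state, cfg), svt(state.X - state.A, 2.0), atol=1e-12
        )


class TestUpdateR:
    def test_group_row_closed_form(self):
        n, m = 4, 2
        state = ADMMState(
            X=np.zeros((n, m)),
            Q=np.zeros((n, m)),
            R=np.zeros((n, m), complex),
            A=np.zeros((n, m)),
            B=np.zeros((n, m), complex),
        )
        # craft C = FX - B directly through B (X = 0)
        C = np.zeros((n, m), complex)
        C[0] = [3.0, 4.0]  # norm 5
        C[1] = [0.6, 0.8]  # norm 1
        state.B = -C
        w = SpectralWeights(n, threshold_bin=n, low_weight=1.0)  # all bins weight 1
        cfg = SolverConfig(lam=2.0, mu_b=1.0, sparsity_mode="group")
        R = update_r(state, w, cfg)
        np.testing.assert_allclose(R[0], C[0] * 3 / 5, atol=1e-12)
        np.testing.assert_allclose(R[1], 0.0, atol=1e-12)

    def test_entrywise_matches_scalar_prox_oracle(self, rng):
        n, m = 6, 4
        state = make_state(rng, n, m)
        w = SpectralWeights(n, threshold_bin=1, high_weight=3.0, low_weight=0.5)
        cfg = SolverConfig(lam=0.8, mu_b=1.3, sparsity_mode="entrywise")
        R = update_r(state, w, cfg)
        C = unitary_dft(state.X) - state.B
        gamma = cfg.lam * w.weights / cfg.mu_b
        for i in range(n):
            for j in range(m):
                expected = prox_l1_complex_numeric(complex(C[i, j]), gamma[i])
                assert abs(R[i, j] - expected) < 1e-4

    def test_group_matches_row_prox_oracle(self, rng):
        n, m = 6, 4
        state = make_state(rng, n, m)
        w = SpectralWeights(n, threshold_bin=2, high_weight=4.0, low_weight=1.0)
        cfg = SolverConfig(lam=0.6, mu_b=0.9, sparsity_mode="group")
        R = update_r(state, w, cfg)
        C = unitary_dft(state.X) - state.B
        gamma = cfg.lam * w.weights / cfg.mu_b
        for i in range(n):
            expected = prox_group_row_numeric(C[i], gamma[i])
            assert np.max(np.abs(R[i] - expected)) < 1e-4


class TestMultipliers:
    def test_zero_residual_leaves_multipliers(self, rng):
        state = make_state(rng)
        state.Q = state.X.copy()
        state.R = unitary_dft(state.X)
        out = update_multipliers(state)
        np.testing.assert_allclose(out.A, state.A, atol=1e-12)
        np.testing.assert_allclose(out.B, state.B, atol=1e-12)

    def test_residual_accumulates_additively(self, rng):
        state = make_state(rng)
        state.A = np.zeros_like(state.A)
        M = state.Q - state.X
        once = update_multipliers(state)
        np.testing.assert_allclose(once.A, M, atol=1e-12)
        twice = update_multipliers(once)
        np.testing.assert_allclose(twice.A, 2 * M, atol=1e-12)
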