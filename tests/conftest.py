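import os
import sys

import numpy as np
import pytest

sys.path.insert(0, os.path.dirname(__file__))

from gaitfill import (
    GaitSimConfig,
    ObservationMask,
    SolverConfig,
    SpectralWeights,
    TrajectoryMatrix,
    generate_trajectories,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20200813)


def make_standard_instance(seed: int = 3):
    """The reference noiseless instance: 4 markers (12 channels), 200 frames,
    two shared harmonics of a 100-frame cycle (rank <= 4), one 20-frame
    occlusion gap per marker."""
    cfg = GaitSimConfig(
        n_markers=4,
        n_frames=200,
        cycle_frames=100,
        n_harmonics=2,
        latent_rank=4,
        offset_range=(0.0, 0.0),
        rng_seed=seed,
    )
    _, truth = generate_trajectories(cfg)
    observed = np.ones_like(truth.values, dtype=bool)
    gap_rng = np.random.default_rng(seed + 1000)
    for k in range(cfg.n_markers):
        s = int(gap_rng.integers(0, cfg.n_frames - 20 + 1))
        observed[s : s + 20, 3 * k : 3 * k + 3] = False
    Y = truth.values.copy()
    Y[~observed] = np.nan
    gapped = TrajectoryMatrix(Y, truth.frame_rate, list(truth.marker_names))
    weights = SpectralWeights(cfg.n_frames, threshold_bin=6)
    return gapped, ObservationMask(observed), truth, weights


@pytest.fixture(scope="session")
def standard_instance():
    return make_standard_instance()


@pytest.fixture
def solver_cfg():
    return SolverConfig(lam=10.0, max_iter=500, tol=1e-8)
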