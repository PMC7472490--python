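"""Error metric, repeated-gap harness, paired statistics, lambda sweep."""

import numpy as np
import pytest

from gaitfill import (
    GaitSimConfig,
    GapSpec,
    ObservationMask,
    SolverConfig,
    TrajectoryMatrix,
    compare_methods,
    lambda_sweep,
    reconstruction_error,
    run_experiment,
)
from gaitfill.evaluation import ErrorReport, default_theta_f

SMALL_SIM = GaitSimConfig(
    n_markers=6, n_frames=300, cycle_frames=100, n_harmonics=3, latent_rank=4,
    noise_sd=0.5, rng_seed=42,
)
FAST_SOLVER = SolverConfig(lam=100.0, tol=1e-4, max_iter=80)


def two_marker_pair(offset):
    truth = np.zeros((10, 6))
    rec = truth.copy()
    observed = np.ones((10, 6), bool)
    observed[4, 0:3] = False
    rec[4, 0:3] = offset
    t = TrajectoryMatrix(truth, 240.0, ["A", "B"])
    r = TrajectoryMatrix(rec, 240.0, ["A", "B"])
    return r, t, ObservationMask(observed)


class TestReconstructionError:
    def test_perfect_recovery_scores_zero(self):
        r, t, m = two_marker_pair((0.0, 0.0, 0.0))
        rep = reconstruction_error(r, t, m)
        assert rep.mean_error == 0.0

    def test_345_triangle(self):
        r, t, m = two_marker_pair((3.0, 4.0, 0.0))
        rep = reconstruction_error(r, t, m)
        assert rep.mean_error == pytest.approx(5.0)
        assert rep.per_entry_errors == [("A", 4, 5.0)]

    def test_mean_matches_hand_computed_average(self, rng):
        truth = np.zeros((20, 3))
        observed = np.ones((20, 3), bool)
        offsets = rng.standard_normal((10, 3))
        rec = truth.copy()
        frames = np.arange(10)
        observed[frames] = False
        rec[frames] = offsets
        rep = reconstruction_error(
            TrajectoryMatrix(rec, 240.0, ["A"]),
            TrajectoryMatrix(truth, 240.0, ["A"]),
            ObservationMask(observed),
        )
        expected = np.mean(np.linalg.norm(offsets, axis=1))
        assert rep.mean_error == pytest.approx(expected, abs=1e-12)

    def test_no_missing_entries_warns_and_returns_empty(self):
        r, t, _ = two_marker_pair((0, 0, 0))
        with pytest.warns(UserWarning, match="no missing"):
            rep = reconstruction_error(r, t, ObservationMask(np.ones((10, 6), bool)))
        assert rep.per_entry_errors == []

    def test_observed_entries_do_not_contribute(self):
        # fidelity means observed positions are identical; only gaps count
        r, t, m = two_marker_pair((3.0, 4.0, 0.0))
        rep = reconstruction_error(r, t, m)
        assert len(rep.per_entry_errors) == 1


class TestCompareMethods:
    def make_reports(self, a, b):
        return [
            ErrorReport(per_repetition_means=list(a), method="A"),
            ErrorReport(per_repetition_means=list(b), method="B"),
        ]

    def test_identical_errors_give_degenerate_p_one(self):
        reports = self.make_reports(np.ones(20), np.ones(20))
        with pytest.warns(UserWarning, match="zero"):
            out = compare_methods(reports)
        assert out[0].p_value == 1.0
        assert not out[0].significant

    def test_constant_shift_is_highly_significant(self, rng):
        base = rng.uniform(5, 10, size=20)
        out = compare_methods(self.make_reports(base, base + 5.0))
        assert out[0].p_value < 1e-3

    def test_antisymmetric_differences_not_significant(self):
        base = np.full(20, 10.0)
        d = np.concatenate([np.full(10, 2.0), np.full(10, -2.0)])
        out = compare_methods(self.make_reports(base, base + d))
        assert out[0].p_value > 0.5

    def test_one_sided_alternative_direction(self, rng):
        base = rng.uniform(5, 10, size=20)
        better_first = compare_methods(self.make_reports(base, base + 5.0), alternative="less")
        assert better_first[0].p_value < 1e-3

    def test_unpaired_inputs_rejected(self):
        reports = self.make_reports(np.ones(20), np.ones(15))
        with pytest.raises(ValueError, match="paired"):
            compare_methods(reports)


class TestRunExperiment:
    def test_shapes_determinism_and_pairing(self):
        spec = GapSpec(repetitions=3, rng_seed=0)
        r1 = run_experiment(SMALL_SIM, spec, ["gs-lr", "pca"], solver_cfg=FAST_SOLVER)
        r2 = run_experiment(SMALL_SIM, spec, ["gs-lr", "pca"], solver_cfg=FAST_SOLVER)
        assert all(len(r.per_repetition_means) == 3 for r in r1)
        for a, b in zip(r1, r2):
            assert a.per_repetition_means == b.per_repetition_means

    def test_marker_subset_restricts_channels(self):
        spec = GapSpec(repetitions=1, rng_seed=0)
        subset = ["M00", "M02", "M04"]
        reports = run_experiment(
            SMALL_SIM, spec, ["pca"], marker_subset=subset, solver_cfg=FAST_SOLVER
        )
        markers = {m for (m, _, _) in reports[0].per_entry_errors}
        assert markers <= set(subset)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown method"):
            run_experiment(SMALL_SIM, GapSpec(repetitions=1), ["kalman"])

    def test_default_theta_f_covers_harmonics(self):
        tf = default_theta_f(SMALL_SIM)
        highest_bin = SMALL_SIM.n_harmonics * SMALL_SIM.n_frames // SMALL_SIM.cycle_frames
        assert tf >= highest_bin


class TestLambdaSweep:
    def make_instance(self):
        from gaitfill import generate_trajectories, simulate_gaps

        observable, truth = generate_trajectories(SMALL_SIM)
        gapped, mask, _ = simulate_gaps(
            observable, GapSpec(repetitions=1, rng_seed=5), SMALL_SIM.cycle_frames
        )
        return gapped, mask, truth

    def test_zero_lambda_runs_as_pure_low_rank(self):
        inst = self.make_instance()
        res = lambda_sweep(inst, [0.0], "s-lr", FAST_SOLVER, theta_f=5)
        assert np.isfinite(res.best_error)

    def test_table_has_one_row_per_lambda_and_reports_argmin(self):
        inst = self.make_instance()
        res = lambda_sweep(inst, [0.0, 10.0, 1e12], "gs-lr", FAST_SOLVER, theta_f=5)
        assert list(res.table["lam"]) == [0.0, 10.0, 1e12]
        assert res.best_error == res.table["mean_error"].min()

    def test_rejects_empty_or_unsorted(self):
        inst = self.make_instance()
        with pytest.raises(ValueError, match="empty"):
            lambda_sweep(inst, [], "s-lr")
        with pytest.raises(ValueError, match="sorted"):
            lambda_sweep(inst, [10.0, 1.0], "s-lr")
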