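import numpy as np
import pytest

from ecograde.markov import (
    CalibrationPoint,
    MarkovError,
    TransitionMatrix,
    dynamic_evaluate,
    fit_transition_matrix,
    objective_q,
    propagate,
    read_calibration,
)
from ecograde.sampler import RandomSource


@pytest.fixture
def absorbing_matrix():
    return TransitionMatrix(np.array([
        [1.0, 0.0, 0.0, 0.0, 0.0],
        [0.3, 0.55, 0.15, 0.0, 0.0],
        [0.2, 0.25, 0.45, 0.1, 0.0],
        [0.0, 0.1, 0.3, 0.5, 0.1],
        [0.0, 0.0, 0.0, 0.0, 1.0],
    ]))


@pytest.fixture
def interior_initial():
    return np.array([0.1, 0.3, 0.3, 0.2, 0.1])


class TestTransitionMatrix:
    def test_rows_must_sum_to_one(self):
        m = np.full((5, 5), 0.2)
        m[0, 0] = 0.5
        with pytest.raises(MarkovError, match="sum to 1"):
            TransitionMatrix(m)

    def test_entries_must_be_probabilities(self):
        m = np.eye(5)
        m[1, 0], m[1, 1] = -0.2, 1.2
        with pytest.raises(MarkovError):
            TransitionMatrix(m)

    def test_power_by_repeated_multiplication(self, absorbing_matrix):
        p3 = absorbing_matrix.power(3)
        expected = absorbing_matrix.entries @ absorbing_matrix.entries @ absorbing_matrix.entries
        np.testing.assert_allclose(p3, expected)
        np.testing.assert_allclose(absorbing_matrix.power(0), np.eye(5))


class TestPropagate:
    def test_identity_matrix_fixed_point(self, interior_initial):
        traj = propagate(interior_initial, TransitionMatrix(np.eye(5)), 5)
        for state in traj.states:
            np.testing.assert_allclose(state, interior_initial)

    def test_absorbing_unit_vectors_are_fixed_points(self, absorbing_matrix):
        for unit in (np.eye(5)[0], np.eye(5)[4]):
            traj = propagate(unit, absorbing_matrix, 6)
            for state in traj.states:
                np.testing.assert_allclose(state, unit, atol=1e-12)

    def test_single_step_hand_product(self):
        m = np.eye(5)
        m[1] = [0.3, 0.6, 0.1, 0.0, 0.0]
        traj = propagate([0, 1, 0, 0, 0], TransitionMatrix(m), 1)
        np.testing.assert_allclose(traj.states[1], [0.3, 0.6, 0.1, 0.0, 0.0])

    def test_mass_conservation(self, absorbing_matrix, interior_initial):
        traj = propagate(interior_initial, absorbing_matrix, 20)
        np.testing.assert_allclose(traj.states.sum(axis=1), 1.0, atol=1e-9)

    def test_zero_steps(self, absorbing_matrix, interior_initial):
        traj = propagate(interior_initial, absorbing_matrix, 0)
        assert len(traj) == 1

    def test_invalid_distribution_rejected(self, absorbing_matrix):
        with pytest.raises(MarkovError):
            propagate([0.5, 0.5, 0.5, 0, 0], absorbing_matrix, 1)
        with pytest.raises(MarkovError):
            propagate([0.2] * 5, absorbing_matrix, -1)


class TestCalibration:
    def test_rows_renormalized_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            point = CalibrationPoint(step=1, observed=np.array([0.3, 0.3, 0.3, 0.2, 0.0]))
        assert point.observed.sum() == pytest.approx(1.0)
        assert any("renormaliz" in r.message for r in caplog.records)

    def test_read_calibration_csv(self):
        text = "step,p1,p2,p3,p4,p5\n1,0.1,0.2,0.3,0.3,0.1\n2,0.2,0.2,0.2,0.2,0.2\n"
        points = read_calibration(text)
        assert [p.step for p in points] == [1, 2]
        np.testing.assert_allclose(points[0].observed, [0.1, 0.2, 0.3, 0.3, 0.1])

    def test_step_must_be_positive(self):
        with pytest.raises(MarkovError):
            CalibrationPoint(step=0, observed=np.array([1, 0, 0, 0, 0.0]))


class TestFitTransitionMatrix:
    def test_trajectory_recovery(self, absorbing_matrix, interior_initial):
        traj = propagate(interior_initial, absorbing_matrix, 4)
        cal = [CalibrationPoint(step=r, observed=traj.states[r]) for r in range(1, 5)]
        fitted, q, diag = fit_transition_matrix(
            interior_initial, cal, restarts=8, seed=0
        )
        assert q <= 0.05
        refit_traj = propagate(interior_initial, fitted, 4)
        np.testing.assert_allclose(
            refit_traj.states[1:], traj.states[1:], atol=0.02
        )

    def test_identity_feasible_gives_zero_q(self, interior_initial):
        cal = [CalibrationPoint(step=1, observed=interior_initial)]
        fitted, q, _ = fit_transition_matrix(
            interior_initial, cal, absorbing_endpoints=False, restarts=4, seed=1
        )
        assert q < 1e-4

    def test_zero_observed_probability_guarded(self, interior_initial):
        cal = [CalibrationPoint(step=1, observed=np.array([0.5, 0.5, 0.0, 0.0, 0.0]))]
        fitted, q, _ = fit_transition_matrix(interior_initial, cal, restarts=4, seed=0)
        assert np.isfinite(q)

    def test_q_matches_independent_recomputation(self, absorbing_matrix, interior_initial):
        traj = propagate(interior_initial, absorbing_matrix, 3)
        cal = [CalibrationPoint(step=r, observed=traj.states[r]) for r in (1, 3)]
        fitted, q, _ = fit_transition_matrix(interior_initial, cal, restarts=4, seed=2)
        assert q == pytest.approx(objective_q(fitted, interior_initial, cal))

    def test_beats_uniform_interior_start(self, absorbing_matrix, interior_initial):
        traj = propagate(interior_initial, absorbing_matrix, 4)
        cal = [CalibrationPoint(step=r, observed=traj.states[r]) for r in range(1, 5)]
        fitted, q, _ = fit_transition_matrix(interior_initial, cal, restarts=4, seed=0)
        uniform = np.zeros((5, 5))
        uniform[0, 0] = uniform[4, 4] = 1.0
        uniform[1:4] = 0.2
        assert q <= objective_q(uniform, interior_initial, cal) + 1e-9

    def test_monotone_information(self, absorbing_matrix, interior_initial):
        # the sub-objective of the jointly fitted matrix cannot beat the
        # dedicated fit of the original points
        traj = propagate(interior_initial, absorbing_matrix, 3)
        cal12 = [CalibrationPoint(step=r, observed=traj.states[r]) for r in (1, 2)]
        perturbed = np.abs(traj.states[3] + np.array([0.15, -0.05, -0.05, -0.05, 0.0]))
        cal123 = cal12 + [CalibrationPoint(step=3, observed=perturbed)]
        _, q12, _ = fit_transition_matrix(interior_initial, cal12, restarts=8, seed=0)
        m_joint, _, _ = fit_transition_matrix(interior_initial, cal123, restarts=8, seed=0)
        sub_q = objective_q(m_joint, interior_initial, cal12)
        assert sub_q >= q12 - 1e-6

    def test_absorbing_rows_exact(self, absorbing_matrix, interior_initial):
        traj = propagate(interior_initial, absorbing_matrix, 2)
        cal = [CalibrationPoint(step=r, observed=traj.states[r]) for r in (1, 2)]
        fitted, _, _ = fit_transition_matrix(interior_initial, cal, restarts=2, seed=0)
        np.testing.assert_array_equal(fitted.entries[0], np.eye(5)[0])
        np.testing.assert_array_equal(fitted.entries[4], np.eye(5)[4])

    def test_duplicate_steps_rejected(self, interior_initial):
        cal = [
            CalibrationPoint(step=1, observed=interior_initial),
            CalibrationPoint(step=1, observed=interior_initial),
        ]
        with pytest.raises(MarkovError, match="duplicate"):
            fit_transition_matrix(interior_initial, cal)

    def test_empty_calibration_rejected(self, interior_initial):
        with pytest.raises(MarkovError, match="calibration"):
            fit_transition_matrix(interior_initial, [])

    def test_reproducible(self, absorbing_matrix, interior_initial):
        traj = propagate(interior_initial, absorbing_matrix, 2)
        cal = [CalibrationPoint(step=r, observed=traj.states[r]) for r in (1, 2)]
        m1, q1, _ = fit_transition_matrix(interior_initial, cal, restarts=4, seed=9)
        m2, q2, _ = fit_transition_matrix(interior_initial, cal, restarts=4, seed=9)
        np.testing.assert_array_equal(m1.entries, m2.entries)
        assert q1 == q2


class TestDynamicEvaluate:
    def test_pipeline_chains(self, slope_standard, slope_sites, absorbing_matrix):
        target = slope_sites[3]  # near-certain grade II
        start = np.array([0.0, 1.0, 0.0, 0.0, 0.0])
        traj = propagate(start, absorbing_matrix, 3)
        cal = [CalibrationPoint(step=r, observed=traj.states[r]) for r in (1, 2, 3)]
        probs, matrix, out_traj, diag = dynamic_evaluate(
            target, slope_standard, cal, steps=3,
            n_trials=400, rng=RandomSource(4), restarts=6, seed=4,
        )
        np.testing.assert_allclose(out_traj.states[0], probs.p)
        assert probs.modal_grade == "II"
        # calibration moves mass II -> I, so later states shift toward I
        assert out_traj.states[-1][0] > out_traj.states[0][0]
        np.testing.assert_allclose(out_traj.states.sum(axis=1), 1.0, atol=1e-9)

    def test_zero_steps_trajectory(self, slope_standard, slope_sites):
        start = np.array([0.0, 1.0, 0.0, 0.0, 0.0])
        cal = [CalibrationPoint(step=1, observed=start)]
        probs, _, traj, _ = dynamic_evaluate(
            slope_sites[3], slope_standard, cal, steps=0,
            n_trials=200, rng=RandomSource(4), restarts=2, seed=0,
        )
        assert len(traj) == 1
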