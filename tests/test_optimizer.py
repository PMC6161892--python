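import numpy as np
import pytest

from residyn import (MarkerSet, OptProblem, SolverOptions, Trajectory,
                     constraint_vector, differentiate_frames, forward_kinematics,
                     initial_guess_from_markers, make_trial, objective_J,
                     run_inverse_dynamics, solve)


class TestInitialGuess:
    def test_exact_inverse_on_clean_markers(self, trial):
        q0 = initial_guess_from_markers(trial.model, trial.S_clean)
        np.testing.assert_allclose(q0.Q, trial.Q_true.Q, atol=1e-12)

    def test_translation_moves_only_hip_coordinates(self, trial):
        shift = np.array([0.7, -0.2])
        moved = MarkerSet(trial.S_clean.labels, trial.S_clean.S + shift,
                          trial.S_clean.dt)
        q0 = initial_guess_from_markers(trial.model, trial.S_clean)
        q1 = initial_guess_from_markers(trial.model, moved)
        np.testing.assert_allclose(q1.Q[:, :7], q0.Q[:, :7], atol=1e-12)
        np.testing.assert_allclose(
            q1.Q[:, 7:9] - q0.Q[:, 7:9],
            np.broadcast_to(shift, q0.Q[:, 7:9].shape), atol=1e-12)

    def test_angle_noise_matches_first_order_propagation(self, model):
        # static pose, many frames: a segment angle estimated from two noisy
        # endpoint markers has RMS error ~ sigma*sqrt(2)/L
        from residyn.synth import add_marker_noise

        sigma = 0.005
        N = 4000
        Q = np.tile([-0.3, -1.7, -1.4, -0.2, -1.5, -1.6, 1.57, 0.0, 0.9], (N, 1))
        frames = forward_kinematics(model, Q)
        clean = MarkerSet(model.marker_labels, frames.S, 0.01)
        noisy = add_marker_noise(clean, sigma, seed=3)
        q0 = initial_guess_from_markers(model, noisy)
        L = model.segment("shank_r").length
        rms = np.sqrt(np.mean((q0.Q[:, 1] - Q[:, 1]) ** 2))
        assert rms == pytest.approx(sigma * np.sqrt(2) / L, rel=0.15)

    def test_missing_marker_raises(self, trial):
        broken = MarkerSet(trial.S_clean.labels[1:], trial.S_clean.S[:, 1:],
                           trial.S_clean.dt)
        with pytest.raises((KeyError, ValueError)):
            initial_guess_from_markers(trial.model, broken)


class TestObjective:
    def test_zero_at_perfect_match(self, trial):
        assert objective_J(trial.Q_true, trial.model, trial.S_clean) == 0.0

    def test_single_centimetre_offset(self, trial):
        S = trial.S_clean.S.copy()
        S[5, 2, 0] += 0.01
        meas = MarkerSet(trial.S_clean.labels, S, trial.S_clean.dt)
        assert objective_J(trial.Q_true, trial.model, meas) == pytest.approx(1e-4)

    def test_matches_naive_double_loop(self, trial, rng):
        S = trial.S_clean.S + rng.normal(0, 0.01, trial.S_clean.S.shape)
        w = rng.uniform(0.5, 2.0, len(trial.S_clean.labels))
        meas = MarkerSet(trial.S_clean.labels, S, trial.S_clean.dt, weights=w)
        frames = forward_kinematics(trial.model, trial.Q_true.Q)
        J_naive = 0.0
        for i in range(meas.n_frames):
            for j in range(len(meas.labels)):
                J_naive += w[j] * np.sum((frames.S[i, j] - S[i, j]) ** 2)
        assert objective_J(trial.Q_true, trial.model, meas) == pytest.approx(J_naive)


class TestConstraintVector:
    def test_length_is_three_per_interior_node(self, trial):
        c = constraint_vector(trial.Q_true, trial.model, trial.loads)
        assert c.shape == (3 * (trial.Q_true.n_nodes - 2),)
        t100 = make_trial(seed=2, n_nodes=100)
        assert constraint_vector(t100.Q_true, t100.model, t100.loads).shape == (294,)

    def test_zero_on_consistent_trial(self, trial):
        c = constraint_vector(trial.Q_true, trial.model, trial.loads)
        assert np.max(np.abs(c)) < 1e-9

    def test_known_force_perturbation_shifts_scaled_entries(self, trial):
        loads2 = trial.loads.copy()
        stance = ~loads2.right.swing
        loads2.right.F[stance, 1] += 25.0
        c = constraint_vector(trial.Q_true, trial.model, loads2)
        cy = c.reshape(-1, 3)[:, 1]
        inner = stance[1:-1]
        expected = -25.0 / trial.model.body_weight
        np.testing.assert_allclose(cy[inner], expected, atol=1e-9)
        np.testing.assert_allclose(cy[~inner], 0.0, atol=1e-9)


class TestSolve:
    def test_consistent_start_returns_initial_guess(self, trial):
        prob = OptProblem(trial.model, trial.S_clean, trial.loads, trial.Q_true.copy())
        out = solve(prob)
        assert out.converged
        assert np.max(np.abs(out.Q_opt.Q - trial.Q_true.Q)) < 1e-8
        assert out.J <= 1e-16

    def test_noisy_stride_converges_with_loads_untouched(self, trial):
        q0 = initial_guess_from_markers(trial.model, trial.S_noisy)
        before = (trial.loads.right.F.tobytes(), trial.loads.right.cop.tobytes(),
                  trial.loads.left.F.tobytes(), trial.loads.left.cop.tobytes())
        out = solve(OptProblem(trial.model, trial.S_noisy, trial.loads, q0))
        after = (trial.loads.right.F.tobytes(), trial.loads.right.cop.tobytes(),
                 trial.loads.left.F.tobytes(), trial.loads.left.cop.tobytes())
        assert out.converged
        assert out.max_constraint_violation <= 1e-6
        assert before == after
        # the optimized kinematics really pass a classical analysis cleanly
        res = run_inverse_dynamics(trial.model, differentiate_frames(trial.model,
                                                                     out.Q_opt),
                                   trial.loads)
        assert np.max(np.abs(res.F_res)) <= 1e-6 * trial.model.body_weight
        # marker adjustments are centimetre-scale for 5 mm noise
        from residyn import rms_marker
        S_opt = forward_kinematics(trial.model, out.Q_opt.Q).S
        adj = rms_marker(trial.S_noisy.S, S_opt)
        assert 0.001 < np.mean(adj) < 0.03

    def test_objective_not_worse_than_first_feasible_iterate(self, trial):
        q0 = initial_guess_from_markers(trial.model, trial.S_noisy)
        out = solve(OptProblem(trial.model, trial.S_noisy, trial.loads, q0))
        feasible = [e["J"] for e in out.log if e["viol"] <= 1e-6]
        assert feasible and out.J <= feasible[0] * (1 + 1e-9)

    def test_weight_scaling_leaves_solution_unchanged(self, trial):
        q0 = initial_guess_from_markers(trial.model, trial.S_noisy)
        scaled = MarkerSet(trial.S_noisy.labels, trial.S_noisy.S, trial.S_noisy.dt,
                           weights=trial.S_noisy.weights * 41.0)
        o1 = solve(OptProblem(trial.model, trial.S_noisy, trial.loads, q0.copy()))
        o2 = solve(OptProblem(trial.model, scaled, trial.loads, q0.copy()))
        np.testing.assert_allclose(o1.Q_opt.Q, o2.Q_opt.Q, atol=1e-4)

    def test_deterministic_given_inputs(self, trial):
        q0 = initial_guess_from_markers(trial.model, trial.S_noisy)
        o1 = solve(OptProblem(trial.model, trial.S_noisy, trial.loads, q0.copy()))
        o2 = solve(OptProblem(trial.model, trial.S_noisy, trial.loads, q0.copy()))
        np.testing.assert_array_equal(o1.Q_opt.Q, o2.Q_opt.Q)

    def test_generic_backend_agrees(self):
        # cross-check the structured SQP against scipy's trust-constr on a
        # short stride: same constrained optimum
        tr = make_trial(seed=3, n_nodes=40)
        q0 = initial_guess_from_markers(tr.model, tr.S_noisy)
        o_sqp = solve(OptProblem(tr.model, tr.S_noisy, tr.loads, q0.copy()))
        o_tc = solve(OptProblem(tr.model, tr.S_noisy, tr.loads, q0.copy(),
                                SolverOptions(method="trust-constr", max_iter=300)))
        assert o_sqp.converged and o_tc.converged
        assert o_tc.max_constraint_violation <= 1e-6
        np.testing.assert_allclose(o_sqp.Q_opt.Q, o_tc.Q_opt.Q, atol=1e-3)
        assert o_sqp.J == pytest.approx(o_tc.J, rel=1e-4)

    def test_grid_mismatch_rejected(self, trial):
        q0 = initial_guess_from_markers(trial.model, trial.S_noisy)
        with pytest.raises(ValueError):
            OptProblem(trial.model, trial.S_noisy,
                       trial.loads.window(0, trial.loads.n_frames - 2), q0)
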