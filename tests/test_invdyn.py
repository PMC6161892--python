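import numpy as np
import pytest

from residyn import (Trajectory, differentiate_frames, run_inverse_dynamics,
                     segment_solve, whole_body_residual)
from residyn.invdyn import _cross
from residyn.model import SEGMENT_NAMES, SegmentParams
from residyn.preprocess import ExternalLoads, FootLoads


def _random_loads(n, rng, swing_free=True):
    def foot():
        F = rng.normal(0, 300, size=(n, 2))
        cop = rng.normal(0, 0.3, size=(n, 2))
        return FootLoads(F, cop, np.zeros(n, bool))

    return ExternalLoads(foot(), foot(), 0.01)


def _random_trial(model, rng, n=20):
    Q = np.zeros((n, 9))
    t = 0.01 * np.arange(n)
    for k in range(7):
        Q[:, k] = rng.normal(0, 1) + 0.3 * np.sin(2 * np.pi * rng.uniform(0.5, 2) * t
                                                  + rng.uniform(0, 6))
    Q[:, 7] = 1.2 * t + 0.02 * np.sin(2 * np.pi * t)
    Q[:, 8] = 0.9 + 0.02 * np.cos(2 * np.pi * t)
    frames = differentiate_frames(model, Trajectory(Q, 0.01))
    return frames, _random_loads(n, rng)


class TestSegmentSolve:
    seg = SegmentParams("foot_r", 1.0, 0.2, 0.5, 0.004)

    def test_static_equilibrium(self):
        # ground force m*|g| straight up through the COM, COM at rest
        z = np.array([0.1, 0.05])
        F_ext = np.array([0.0, 9.81])
        F, T = segment_solve(self.seg, np.zeros(2), 0.0, z, np.array([0.0, 0.05]),
                             applied_forces=((F_ext, np.array([0.1, 0.0])),))
        np.testing.assert_allclose(F, 0.0, atol=1e-12)
        assert T == pytest.approx(0.0, abs=1e-12)

    def test_free_fall(self):
        F, T = segment_solve(self.seg, np.array([0.0, -9.81]), 0.0,
                             np.array([0.3, 1.0]), np.array([0.2, 1.1]))
        np.testing.assert_allclose(F, 0.0, atol=1e-12)
        assert T == 0.0

    def test_back_substitution_closes_equations(self, rng):
        # plug the solved proximal load back into Newton-Euler: residual < 1e-10
        for _ in range(50):
            a = rng.normal(size=2)
            alpha = rng.normal()
            z = rng.normal(size=2)
            prox = rng.normal(size=2)
            loads = [(rng.normal(0, 100, 2), rng.normal(size=2)) for _ in range(3)]
            torques = [rng.normal()]
            g = np.array([0.0, -9.81])
            F, T = segment_solve(self.seg, a, alpha, z, prox, loads, torques, g)
            f_sum = self.seg.mass * g + F + sum(Fi for Fi, _ in loads)
            t_sum = T + _cross(prox - z, F) + sum(torques) \
                + sum(_cross(r - z, Fi) for Fi, r in loads)
            assert np.max(np.abs(f_sum - self.seg.mass * a)) < 1e-10
            assert abs(t_sum - self.seg.inertia_com * alpha) < 1e-10


class TestRunInverseDynamics:
    def test_consistent_trial_has_zero_residuals(self, trial):
        fr = differentiate_frames(trial.model, trial.Q_true)
        res = run_inverse_dynamics(trial.model, fr, trial.loads)
        bw = trial.model.body_weight
        assert np.max(np.abs(res.F_res)) < 1e-9 * bw
        assert np.max(np.abs(res.T_res)) < 1e-9 * bw * trial.model.segment("trunk").length

    def test_residual_point_changes_torque_not_force(self, model, rng):
        frames, loads = _random_trial(model, rng)
        r1 = run_inverse_dynamics(model, frames, loads, "shoulder")
        r2 = run_inverse_dynamics(model, frames, loads, "trunk_com")
        np.testing.assert_array_equal(r1.F_res, r2.F_res)
        # torques differ by the moment of F_res over the point shift
        shift = r1.residual_point_xy - r2.residual_point_xy
        np.testing.assert_allclose(r2.T_res, r1.T_res + _cross(shift, r1.F_res),
                                   atol=1e-9)
        assert np.max(np.abs(r1.T_res - r2.T_res)) > 1.0  # the choice matters

    def test_point_shift_identity_machine_precision(self, model, rng):
        frames, loads = _random_trial(model, rng)
        r1 = run_inverse_dynamics(model, frames, loads, "shoulder")
        r2 = run_inverse_dynamics(model, frames, loads, "trunk_com")
        P1, P2 = r1.residual_point_xy, r2.residual_point_xy
        lhs = r2.T_res - r1.T_res
        rhs = _cross(P1 - P2, r1.F_res)
        scale = np.max(np.abs(r1.T_res)) + 1.0
        np.testing.assert_allclose(lhs, rhs, atol=1e-10 * scale)

    def test_grid_mismatch_raises(self, trial):
        fr = differentiate_frames(trial.model, trial.Q_true)
        short = trial.loads.window(0, trial.loads.n_frames - 2)
        with pytest.raises(ValueError, match="grid"):
            run_inverse_dynamics(trial.model, fr, short)

    def test_action_reaction_through_the_chain(self, model, rng):
        # the hip-branch forces transmitted to the trunk close the whole-body
        # force balance exactly (Newton's third law bookkeeping)
        frames, loads = _random_trial(model, rng)
        res = run_inverse_dynamics(model, frames, loads)
        F_wb, _, _ = whole_body_residual(model, frames, loads)
        np.testing.assert_allclose(res.F_res, F_wb, atol=1e-9)


class TestWholeBodyOracle:
    def test_recursion_equals_summation_on_random_trials(self, model):
        rng = np.random.default_rng(99)
        for _ in range(100):
            frames, loads = _random_trial(model, rng)
            res = run_inverse_dynamics(model, frames, loads)
            F_wb, T_wb, _ = whole_body_residual(model, frames, loads)
            fscale = np.max(np.abs(F_wb)) + model.body_weight
            tscale = np.max(np.abs(T_wb)) + model.body_weight
            assert np.max(np.abs(res.F_res - F_wb)) < 1e-9 * fscale
            assert np.max(np.abs(res.T_res - T_wb)) < 1e-9 * tscale

    def test_constant_force_perturbation_superposes(self, trial):
        fr = differentiate_frames(trial.model, trial.Q_true)
        loads2 = trial.loads.copy()
        stance = ~loads2.right.swing
        loads2.right.F[stance, 0] += 10.0
        F2, _, _ = whole_body_residual(trial.model, fr, loads2)
        F1, _, _ = whole_body_residual(trial.model, fr, trial.loads)
        inner = stance[1:-1]
        np.testing.assert_allclose((F2 - F1)[inner, 0], -10.0, atol=1e-10)
        np.testing.assert_allclose((F2 - F1)[~inner], 0.0, atol=1e-10)

    def test_kinematic_noise_maps_linearly_to_residual(self, trial, rng):
        # perturb only the hip translation: delta F_res = sum_k m_k * delta a
        dq = rng.normal(0, 0.005, size=(trial.Q_true.n_nodes, 2))
        Q2 = trial.Q_true.Q.copy()
        Q2[:, 7:9] += dq
        fr2 = differentiate_frames(trial.model, Trajectory(Q2, trial.Q_true.dt))
        F2, _, _ = whole_body_residual(trial.model, fr2, trial.loads)
        from residyn import central_second_difference
        da = central_second_difference(dq, trial.Q_true.dt)[1:-1]
        expected = trial.model.masses.sum() * da
        np.testing.assert_allclose(F2, expected, atol=1e-4)


def test_pendulum_roundtrip_is_second_order():
    from _pendulum import inverse_torque_error

    e_coarse = inverse_torque_error(0.004)
    e_fine = inverse_torque_error(0.002)
    assert e_coarse / e_fine == pytest.approx(4.0, rel=0.15)
    assert e_fine < 0.01
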