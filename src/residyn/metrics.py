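"""Comparison measures between classical and residual-free analyses.

Three RMS measures quantify how much the optimization changed the data:
per-coordinate RMS of the generalized coordinates, per-marker RMS of the
Cartesian marker displacement, and a per-joint *relative* torque RMS
(normalized by the RMS of the classical torque series, so it is deliberately
asymmetric in its arguments). Powers follow the standard definitions: joint
power is net joint torque times the joint angular velocity (distal minus
proximal segment angular velocity); residual power is the residual torque
times the trunk angular velocity plus the residual force dotted with the
velocity of its application point.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .invdyn import InvDynResult
from .kinematics import central_first_difference
from .model import SEGMENT_NAMES, KinematicsFrames, Trajectory, WalkingModel

__all__ = ["rms_coordinate", "rms_marker", "rms_torque_relative",
           "joint_and_residual_power", "energy_audit", "summary_table"]

# joint -> (distal segment, proximal segment) for the angular-velocity convention
_JOINT_SEGMENTS = {
    "ankle_r": ("foot_r", "shank_r"), "knee_r": ("shank_r", "thigh_r"),
    "hip_r": ("thigh_r", "trunk"),
    "ankle_l": ("foot_l", "shank_l"), "knee_l": ("shank_l", "thigh_l"),
    "hip_l": ("thigh_l", "trunk"),
}


def _check_same_length(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"series shapes differ: {a.shape} vs {b.shape}")


def rms_coordinate(q_before: np.ndarray, q_after: np.ndarray) -> np.ndarray:
    """Per-DOF RMS difference of two coordinate series (rad or m).

    Accepts (N,) or (N, n) arrays; returns a scalar or per-column vector.
    """
    a, b = np.asarray(q_before, float), np.asarray(q_after, float)
    _check_same_length(a, b)
    return np.sqrt(np.mean((a - b) ** 2, axis=0))


def rms_marker(S_before: np.ndarray, S_after: np.ndarray) -> np.ndarray:
    """Per-marker RMS Cartesian distance (m) between two (N, c, 2) marker arrays."""
    a, b = np.asarray(S_before, float), np.asarray(S_after, float)
    _check_same_length(a, b)
    return np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1), axis=0))


def rms_torque_relative(T_before: np.ndarray, T_after: np.ndarray) -> float:
    """Relative torque change: RMS(T - T') normalized by RMS(T').

    ``T_after`` is the classical (reference) series and supplies the
    normalizer. Returns NaN (flagged undefined) if the reference torque is
    identically zero.
    """
    T, Tp = np.asarray(T_before, float), np.asarray(T_after, float)
    _check_same_length(T, Tp)
    denom = np.sqrt(np.mean(Tp**2))
    if denom == 0.0:
        return float("nan")
    return float(np.sqrt(np.mean((T - Tp) ** 2)) / denom)


def joint_and_residual_power(frames: KinematicsFrames, result: InvDynResult,
                             model: WalkingModel | None = None) -> dict[str, np.ndarray]:
    """Power series (W) on interior nodes for each joint plus the residual.

    Joint angular velocity is distal-segment minus proximal-segment angular
    velocity, so positive power means the torque acts in the direction of the
    relative rotation. The residual power combines the residual torque (times
    trunk angular velocity) with the residual force (times the velocity of its
    application point).
    """
    if frames.omega is None:
        raise ValueError("frames lack angular velocities")
    omega = frames.omega[1:-1]
    powers: dict[str, np.ndarray] = {}
    for joint, T in result.joint_torques.items():
        distal, proximal = _JOINT_SEGMENTS[joint]
        w_rel = omega[:, SEGMENT_NAMES.index(distal)] - omega[:, SEGMENT_NAMES.index(proximal)]
        powers[joint] = T * w_rel
    w_trunk = omega[:, SEGMENT_NAMES.index("trunk")]
    v_point = central_first_difference(
        frames.P["shoulder"] if result.residual_point == "shoulder"
        else frames.Z[:, SEGMENT_NAMES.index("trunk")], frames.dt)[1:-1]
    powers["residual"] = result.T_res * w_trunk + np.sum(result.F_res * v_point, axis=1)
    return powers


def energy_audit(model: WalkingModel, traj: Trajectory, frames: KinematicsFrames,
                 result: InvDynResult, loads) -> dict[str, np.ndarray]:
    """Discrete mechanical energy balance on doubly interior nodes.

    Sums joint torque powers, gravity power, external (ground reaction) power
    at the moving material point under the COP, and residual power, and
    compares against the central-difference rate of change of total kinetic
    energy. On dynamically consistent data the imbalance shrinks as O(dt^2).

    Returns series aligned on nodes ``2 .. N-3``: ``supplied``, ``dE_kin``,
    ``imbalance``.
    """
    dt = traj.dt
    omega = frames.omega          # (N, 7), NaN at boundaries
    v_com = central_first_difference(frames.Z, dt)      # (N, 7, 2)
    # kinetic energy on interior nodes
    Ekin = 0.5 * np.sum(model.masses[None, :] * np.sum(v_com**2, axis=-1), axis=1) \
        + 0.5 * np.sum(model.inertias[None, :] * omega**2, axis=1)
    dEkin = central_first_difference(Ekin[1:-1], dt)[1:-1]    # nodes 2..N-3

    powers = joint_and_residual_power(frames, result, model)
    p_joint = sum(powers[j] for j in result.joint_torques)
    p_res = powers["residual"]
    p_grav = np.sum(model.masses[None, :] * np.sum(
        model.gravity[None, None, :] * v_com[1:-1], axis=-1), axis=1)
    p_ext = np.zeros_like(p_grav)
    for side, foot in loads.feet.items():
        seg = "foot_r" if side == "right" else "foot_l"
        k = SEGMENT_NAMES.index(seg)
        cop = np.where(np.isnan(foot.cop), frames.Z[:, k].real if np.iscomplexobj(frames.Z)
                       else frames.Z[:, k], foot.cop)
        r_rel = (cop - frames.Z[:, k])[1:-1]
        w = frames.omega[1:-1, k]
        # velocity of the foot's material point coinciding with the COP
        v_point = v_com[1:-1, k] + np.stack([-w * r_rel[:, 1], w * r_rel[:, 0]], axis=-1)
        p_ext = p_ext + np.sum(foot.F[1:-1] * v_point, axis=1)

    supplied = (p_joint + p_res + p_grav + p_ext)[1:-1]
    return {"supplied": supplied, "dE_kin": dEkin, "imbalance": supplied - dEkin}


def summary_table(rms_q: dict[str, float], rms_s: dict[str, float],
                  rms_T_rel: dict[str, float]) -> pd.DataFrame:
    """Human-readable summary of the three RMS measures (one row per named
    quantity; units rad, cm and dimensionless respectively)."""
    rows = [{"quantity": f"RMS_q {k}", "value": v, "unit": "rad|m"} for k, v in rms_q.items()]
    rows += [{"quantity": f"RMS_s {k}", "value": 100.0 * v, "unit": "cm"}
             for k, v in rms_s.items()]
    rows += [{"quantity": f"RMS_T,rel {k}", "value": v, "unit": "-"}
             for k, v in rms_T_rel.items()]
    return pd.DataFrame(rows)
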