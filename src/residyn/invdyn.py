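"""Newton-Euler inverse dynamics of the planar walking chain.

The classical bottom-up recursion starts at each foot, where the ground
reaction force and its point of application are known, solves the segment's
three planar equations of motion for the proximal joint force and torque,
reverses them (Newton's third law) and proceeds up the leg. The trunk finally
receives both hip reactions and gravity; whatever force and torque are still
needed to close its balance are the *residual* force and torque — fictitious
loads, conventionally applied at the shoulder or at the trunk COM, that
quantify the inconsistency between measured kinematics and measured external
forces.

:func:`whole_body_residual` provides an independent check: summing Newton's
second law over all segments without any recursion must give the same
residuals, because the internal joint loads cancel pairwise.

All quantities are evaluated on interior time nodes (where central-difference
accelerations exist). The planar cross product is ``r x F = rx*Fy - ry*Fx``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import SEGMENT_NAMES, KinematicsFrames, SegmentParams, WalkingModel
from .preprocess import ExternalLoads

__all__ = ["InvDynResult", "segment_solve", "run_inverse_dynamics",
           "whole_body_residual", "residual_application_point"]

JOINT_NAMES = ("ankle_r", "knee_r", "hip_r", "ankle_l", "knee_l", "hip_l")

_LEG_SEGMENTS = {"right": ("foot_r", "shank_r", "thigh_r"),
                 "left": ("foot_l", "shank_l", "thigh_l")}
_LEG_JOINTS = {"right": ("ankle_r", "knee_r", "hip_r"),
               "left": ("ankle_l", "knee_l", "hip_l")}
# proximal joint *point* of each segment in the recursion order
_LEG_POINTS = {"right": ("ankle_r", "knee_r", "hip"),
               "left": ("ankle_l", "knee_l", "hip")}


def _cross(r, F):
    """Planar cross product, broadcasting over leading axes."""
    return r[..., 0] * F[..., 1] - r[..., 1] * F[..., 0]


@dataclass
class InvDynResult:
    """Net joint loads and trunk residuals on interior nodes.

    ``joint_forces[name]`` is the force exerted *on the distal segment* at the
    joint (shape (M, 2)); ``joint_torques[name]`` the matching net torque.
    ``F_res``/``T_res`` close the trunk's balance, with ``F_res`` acting at
    ``residual_point`` (label and per-node coordinates). ``node_offset`` maps
    row ``i`` to trajectory node ``i + node_offset``.
    """

    joint_forces: dict[str, np.ndarray]
    joint_torques: dict[str, np.ndarray]
    F_res: np.ndarray
    T_res: np.ndarray
    residual_point: str
    residual_point_xy: np.ndarray
    dt: float
    node_offset: int = 1

    @property
    def n_nodes(self) -> int:
        return self.F_res.shape[0]


def segment_solve(seg: SegmentParams, a_com, alpha, com_pos, prox_pos,
                  applied_forces=(), applied_torques=(), gravity=(0.0, -9.81)):
    """Solve one segment's planar Newton-Euler equations for its proximal
    joint force and torque.

    ``applied_forces`` is a sequence of ``(F, point)`` pairs (each (..., 2));
    ``applied_torques`` a sequence of pure torques. With COM acceleration
    ``a`` and angular acceleration ``alpha``::

        F_prox = m a - m g - sum F_applied
        T_prox = I alpha - sum T_applied - sum (r_F - z) x F_applied
                 - (p_prox - z) x F_prox

    Pure algebra; broadcasts over any leading shape.
    """
    g = np.asarray(gravity)
    a_com = np.asarray(a_com)
    F_prox = seg.mass * (a_com - g)
    T_prox = seg.inertia_com * np.asarray(alpha)
    for T in applied_torques:
        T_prox = T_prox - T
    for F, point in applied_forces:
        F = np.asarray(F)
        F_prox = F_prox - F
        T_prox = T_prox - _cross(np.asarray(point) - com_pos, F)
    T_prox = T_prox - _cross(prox_pos - com_pos, F_prox)
    return F_prox, T_prox


def _interior_loads(loads: ExternalLoads):
    """Per-foot force, sanitized COP and swing mask restricted to interior nodes."""
    out = {}
    for side, foot in loads.feet.items():
        F = foot.F[1:-1]
        cop = np.where(np.isnan(foot.cop), 0.0, foot.cop)[1:-1]
        out[side] = (F, cop, foot.swing[1:-1])
    return out


def residual_application_point(frames: KinematicsFrames, residual_point: str) -> np.ndarray:
    """Interior-node coordinates of the residual force's application point."""
    if residual_point == "shoulder":
        return frames.P["shoulder"][1:-1]
    if residual_point == "trunk_com":
        return frames.Z[1:-1, SEGMENT_NAMES.index("trunk")]
    raise ValueError(f"residual_point must be 'shoulder' or 'trunk_com', got {residual_point!r}")


def run_inverse_dynamics(model: WalkingModel, frames: KinematicsFrames,
                         loads: ExternalLoads,
                         residual_point: str = "shoulder") -> InvDynResult:
    """Classical inverse dynamics of the walking model.

    Recursion foot -> shank -> thigh per leg; the trunk receives the two
    (reversed) hip-branch reactions at the lumped hip and the residual force
    and torque close its balance, the force acting at ``residual_point``
    (``"shoulder"`` by default, or ``"trunk_com"``).
    """
    if frames.Zdd is None or frames.alpha is None:
        raise ValueError("frames lack accelerations; use differentiate_frames")
    if frames.n_nodes != loads.n_frames:
        raise ValueError(f"kinematics ({frames.n_nodes} nodes) and loads "
                         f"({loads.n_frames}) do not share the time grid")
    g = model.gravity
    foot_loads = _interior_loads(loads)
    Z = frames.Z[1:-1]
    Zdd = frames.Zdd[1:-1]
    alpha = frames.alpha[1:-1]

    joint_forces: dict[str, np.ndarray] = {}
    joint_torques: dict[str, np.ndarray] = {}
    hip_reactions = []
    for side in ("right", "left"):
        F_ext, cop, _swing = foot_loads[side]
        F_carry, T_carry, point_carry = F_ext, None, cop
        for seg_name, joint, prox_name in zip(_LEG_SEGMENTS[side], _LEG_JOINTS[side],
                                              _LEG_POINTS[side]):
            k = SEGMENT_NAMES.index(seg_name)
            seg = model.segment(seg_name)
            prox = frames.P[prox_name][1:-1]
            torques = () if T_carry is None else (T_carry,)
            F_prox, T_prox = segment_solve(
                seg, Zdd[:, k], alpha[:, k], Z[:, k], prox,
                applied_forces=((F_carry, point_carry),), applied_torques=torques,
                gravity=g)
            joint_forces[joint] = F_prox
            joint_torques[joint] = T_prox
            # reversed reaction becomes the distal load of the parent segment
            F_carry, T_carry, point_carry = -F_prox, -T_prox, prox
        hip_reactions.append((F_carry, T_carry))

    # trunk: both hip reactions act at the lumped hip point
    k = SEGMENT_NAMES.index("trunk")
    seg = model.segment("trunk")
    hip = frames.P["hip"][1:-1]
    p_res = residual_application_point(frames, residual_point)
    F_res, T_res = segment_solve(
        seg, Zdd[:, k], alpha[:, k], Z[:, k], p_res,
        applied_forces=tuple((F, hip) for F, _ in hip_reactions),
        applied_torques=tuple(T for _, T in hip_reactions),
        gravity=g)

    return InvDynResult(joint_forces, joint_torques, F_res, T_res,
                        residual_point, p_res, frames.dt)


def whole_body_residual(model: WalkingModel, frames: KinematicsFrames,
                        loads: ExternalLoads,
                        residual_point: str = "shoulder"):
    """Residual force and torque from whole-body summation (no recursion).

    Newton: ``F_res = sum_k m_k (a_k - g) - sum F_ext``. Euler about the
    residual application point ``p``::

        T_res = sum_k [ I_k alpha_k + (z_k - p) x m_k (a_k - g) ]
                - sum_f (r_f - p) x F_ext,f

    Internal joint loads cancel pairwise, so this must agree with the
    recursion of :func:`run_inverse_dynamics` to machine precision.
    Returns ``(F_res, T_res, p)`` on interior nodes.
    """
    if frames.Zdd is None or frames.alpha is None:
        raise ValueError("frames lack accelerations; use differentiate_frames")
    g = model.gravity
    m = model.masses
    I = model.inertias
    Z = frames.Z[1:-1]
    Zdd = frames.Zdd[1:-1]
    alpha = frames.alpha[1:-1]
    p = residual_application_point(frames, residual_point)

    net = m[None, :, None] * (Zdd - g)           # (M, 7, 2)
    F_res = net.sum(axis=1)
    T_res = (I[None, :] * alpha).sum(axis=1) + _cross(Z - p[:, None, :], net).sum(axis=1)
    for F_ext, cop, _swing in _interior_loads(loads).values():
        F_res = F_res - F_ext
        T_res = T_res - _cross(cop - p, F_ext)
    return F_res, T_res, p
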