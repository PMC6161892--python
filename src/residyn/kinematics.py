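"""Central-difference differentiation of trajectories.

Accelerations are obtained by applying the three-point central stencil
directly to Cartesian COM positions evaluated per node — *not* by chain-ruling
numerically differentiated generalized coordinates, a variant that trades a
slightly lower mismatch objective for high-frequency oscillations in the
optimized coordinates. Both stencils are exact on polynomials up to degree 2
and second-order accurate otherwise. Boundary nodes, where the stencil does
not fit, are flagged NaN; dynamics and constraints are evaluated on interior
nodes only.
"""

from __future__ import annotations

import numpy as np

from .model import KinematicsFrames, Trajectory, WalkingModel, forward_kinematics

__all__ = ["central_second_difference", "central_first_difference", "differentiate_frames"]


def _check(X: np.ndarray, dt: float) -> np.ndarray:
    X = np.asarray(X)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 nodes for a central difference")
    if dt <= 0:
        raise ValueError("dt must be positive")
    return X


def _nan_padded(interior: np.ndarray, n: int) -> np.ndarray:
    out = np.full((n,) + interior.shape[1:], np.nan,
                  dtype=np.result_type(interior.dtype, float))
    out[1:-1] = interior
    return out


def central_second_difference(X: np.ndarray, dt: float) -> np.ndarray:
    """Second time derivative ``(X[i-1] - 2 X[i] + X[i+1]) / dt**2``.

    Returns an array of the same length with NaN at the two boundary nodes.
    """
    X = _check(X, dt)
    return _nan_padded((X[:-2] - 2.0 * X[1:-1] + X[2:]) / dt**2, X.shape[0])


def central_first_difference(X: np.ndarray, dt: float) -> np.ndarray:
    """First time derivative ``(X[i+1] - X[i-1]) / (2 dt)``, NaN at boundaries."""
    X = _check(X, dt)
    return _nan_padded((X[2:] - X[:-2]) / (2.0 * dt), X.shape[0])


def differentiate_frames(model: WalkingModel, traj: Trajectory) -> KinematicsFrames:
    """Complete Cartesian kinematics: positions plus COM accelerations,
    segment angular velocities and angular accelerations on interior nodes."""
    frames = forward_kinematics(model, traj)
    ang = traj.Q[:, :7]
    frames.Zdd = central_second_difference(frames.Z, traj.dt)
    frames.alpha = central_second_difference(ang, traj.dt)
    frames.omega = central_first_difference(ang, traj.dt)
    return frames
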