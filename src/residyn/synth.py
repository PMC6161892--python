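"""Dynamically consistent synthetic walking trials.

Real treadmill data for this kind of analysis are rarely shareable, and more
importantly no measured trial comes with ground truth. This module therefore
generates walking-*like* planar trials for which consistency holds *exactly on
the discrete grid*: smooth harmonic gait kinematics are drawn first, then the
per-foot ground reaction forces and centers of pressure are computed from the
model's own central-difference accelerations so that the residual force and
torque are zero (to rounding) at every interior node. Gaussian measurement
noise (and optionally a slow sinusoidal skin-artifact term) is then added to
the marker positions, giving every downstream test a certified fixture with
known truth.

Defaults emulate one stride of walking at a comfortable speed: 120 nodes at
100 Hz (1.2 s stride), 5 mm marker noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .invdyn import _cross, run_inverse_dynamics
from .kinematics import differentiate_frames
from .model import (DEFAULT_MARKER_MAP, SEGMENT_NAMES, Trajectory, WalkingModel,
                    build_walking_model, forward_kinematics)
from .preprocess import ExternalLoads, FootLoads, MarkerSet

__all__ = ["SynthTrial", "default_model", "generate_kinematics", "support_schedule",
           "consistent_loads_from_kinematics", "add_marker_noise", "make_trial"]

#: study-scale defaults: subject mass (kg) and symmetric segment lengths (m)
DEFAULT_SUBJECT_MASS = 66.1
DEFAULT_SEGMENT_LENGTHS = {"foot": 0.15, "shank": 0.42, "thigh": 0.41, "trunk": 0.52}


def default_model(subject_mass: float = DEFAULT_SUBJECT_MASS,
                  segment_lengths: dict[str, float] | None = None) -> WalkingModel:
    """The walking model used by the synthetic trials (shipped anthropometrics)."""
    return build_walking_model(subject_mass,
                               dict(DEFAULT_SEGMENT_LENGTHS if segment_lengths is None
                                    else segment_lengths))


@dataclass
class SynthTrial:
    """One synthetic stride: ground-truth trajectory, consistent loads, clean
    and noisy marker sets, and the generator's noise/seed parameters."""

    model: WalkingModel
    Q_true: Trajectory
    loads: ExternalLoads
    S_clean: MarkerSet
    S_noisy: MarkerSet
    sigma: float
    seed: int


def generate_kinematics(model: WalkingModel, n_nodes: int = 120, dt: float = 0.01,
                        stride_duration: float | None = None, speed: float = 1.25,
                        amplitude_scale: float = 1.0, seed: int = 0) -> Trajectory:
    """Smooth gait-like generalized coordinates.

    Sums of low-order harmonics of the stride frequency: thigh/shank/foot
    angles oscillate about the downward vertical with the two legs in
    antiphase, the trunk sways slightly about the upward vertical, and the hip
    drifts forward at ``speed`` with small 2-per-stride excursions. Node 0
    coincides with right toe-off (right leg maximally trailing). The seed
    jitters amplitudes and phases by a few percent, so every seed is a
    distinct but comparable stride; ``amplitude_scale=0`` gives a static
    upright pose. Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    T = n_nodes * dt if stride_duration is None else stride_duration
    t = dt * np.arange(n_nodes)
    phi = 2.0 * np.pi * t / T

    def jit(x, rel=0.08):
        return x * (1.0 + rel * rng.standard_normal())

    a = amplitude_scale
    down, up = -np.pi / 2, np.pi / 2
    ph_t = jit(-np.pi / 2, 0.03) + 0.05 * rng.standard_normal()
    thigh_amp, shank_amp, foot_amp = jit(0.32), jit(0.40), jit(0.45)
    Q = np.empty((n_nodes, 9))
    for side, (i_f, i_s, i_t) in (("r", (0, 1, 2)), ("l", (3, 4, 5))):
        off = 0.0 if side == "r" else np.pi
        Q[:, i_t] = down + a * (thigh_amp * np.sin(phi + ph_t + off)
                                + jit(0.05) * np.sin(2 * phi + off))
        Q[:, i_s] = down + a * (-jit(0.18) + shank_amp * np.sin(phi + ph_t - jit(0.5) + off)
                                + jit(0.12) * np.sin(2 * phi + jit(1.0) + off))
        Q[:, i_f] = jit(-0.25, 0.04) + a * (foot_amp * np.sin(phi + ph_t - jit(0.9) + off)
                                            + jit(0.10) * np.sin(2 * phi + jit(0.7) + off))
    Q[:, 6] = up + a * jit(0.04) * np.sin(2 * phi + jit(0.3))
    leg = model.segment("thigh_r").length + model.segment("shank_r").length
    Q[:, 7] = speed * t + a * jit(0.012) * np.sin(2 * phi + jit(0.2))
    Q[:, 8] = 0.93 * leg + model.segment("foot_r").length * 0.5 \
        + a * jit(0.015) * np.sin(2 * phi + jit(1.5))
    return Trajectory(Q, dt)


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * u * (u * (6.0 * u - 15.0) + 10.0)


def support_schedule(n_nodes: int, dt: float, stride_duration: float | None = None,
                     right_swing: tuple[float, float] = (0.0, 0.35),
                     left_swing: tuple[float, float] = (0.50, 0.85)) -> np.ndarray:
    """Right-foot load share ``lambda(t)`` over (possibly several) strides.

    ``lambda`` is exactly 0 during right swing, exactly 1 during left swing,
    and moves between the plateaus with a smoothstep during double support.
    Fractions are of the stride period; the pattern repeats if the trial spans
    more than one stride.
    """
    T = n_nodes * dt if stride_duration is None else stride_duration
    u = (dt * np.arange(n_nodes) / T) % 1.0
    r0, r1 = right_swing
    l0, l1 = left_swing
    lam = np.zeros(n_nodes)
    rise = (u >= r1) & (u < l0)
    lam[rise] = _smoothstep((u[rise] - r1) / (l0 - r1))
    lam[(u >= l0) & (u < l1)] = 1.0
    fall = u >= l1
    lam[fall] = 1.0 - _smoothstep((u[fall] - l1) / (1.0 - l1))
    return lam


def consistent_loads_from_kinematics(model: WalkingModel, traj: Trajectory,
                                     lam: np.ndarray, ground_y: float = 0.0,
                                     cop_window: float | None = None,
                                     strict: bool = False) -> ExternalLoads:
    """External loads that make ``traj`` exactly consistent on the discrete grid.

    At every interior node the total required force is
    ``F_tot = sum_k m_k (a_k - g)`` with accelerations from the same
    central-difference stencil the inverse dynamics uses. The right foot
    carries ``lam * F_tot``, the left ``(1 - lam) * F_tot``, and the torque
    demand is split in the same proportion, which places both active feet's
    centers of pressure at the common zero-moment point on the walking
    surface. By construction the resulting trial passes inverse dynamics with
    residuals at rounding level.

    If ``cop_window`` is given, the COP is checked to stay within that
    horizontal distance of the supporting foot's ankle; violations warn and
    trigger one retry with sharper support transitions (raise instead when
    ``strict``).
    """
    lam = np.asarray(lam, float)
    if lam.shape != (traj.n_nodes,) or np.any((lam < 0) | (lam > 1)):
        raise ValueError("lambda must be one value in [0, 1] per node")
    frames = differentiate_frames(model, traj)
    m = model.masses
    g = model.gravity
    acc = frames.Zdd[1:-1]
    net = m[None, :, None] * (acc - g)
    F_tot = net.sum(axis=1)                                   # (N-2, 2)
    G_tot = (model.inertias[None, :] * frames.alpha[1:-1]).sum(axis=1) \
        + _cross(frames.Z[1:-1], net).sum(axis=1)             # torque about origin
    if np.any(np.abs(F_tot[:, 1]) < 1e-6):
        raise ValueError("vertical force demand crosses zero; cannot place a COP")
    x_zmp = (G_tot + ground_y * F_tot[:, 0]) / F_tot[:, 1]

    # pad boundary nodes with their nearest interior demand
    F_full = np.vstack([F_tot[:1], F_tot, F_tot[-1:]])
    x_full = np.concatenate([x_zmp[:1], x_zmp, x_zmp[-1:]])

    def foot_loads(share: np.ndarray) -> FootLoads:
        F = share[:, None] * F_full
        swing = share == 0.0
        cop = np.stack([x_full, np.full_like(x_full, ground_y)], axis=-1)
        cop[swing] = np.nan
        return FootLoads(F, cop, swing)

    loads = ExternalLoads(foot_loads(lam), foot_loads(1.0 - lam), traj.dt, traj.t0)

    if cop_window is not None:
        for attempt in range(2):
            bad = _cop_excursion(model, frames, loads, cop_window)
            if not bad:
                break
            msg = (f"center of pressure strays more than {cop_window} m from the "
                   f"supporting ankle at {bad} node(s)")
            if strict and attempt == 1:
                raise ValueError(msg)
            warnings.warn(msg + "; retrying with sharper support transitions"
                          if attempt == 0 else msg)
            if attempt == 0:
                lam = np.round(lam)  # hard single-support schedule
                loads = ExternalLoads(foot_loads(lam), foot_loads(1.0 - lam),
                                      traj.dt, traj.t0)
    return loads


def _cop_excursion(model, frames, loads: ExternalLoads, window: float) -> int:
    bad = 0
    for side, foot in loads.feet.items():
        ankle = frames.P["ankle_r" if side == "right" else "ankle_l"]
        active = ~foot.swing
        bad += int(np.sum(np.abs(foot.cop[active, 0] - ankle[active, 0]) > window))
    return bad


def add_marker_noise(markers: MarkerSet, sigma: float, seed: int,
                     artifact_amplitude: float = 0.0,
                     artifact_freq_hz: float = 1.0) -> MarkerSet:
    """Corrupt a marker set with i.i.d. Gaussian noise per coordinate (std
    ``sigma`` m) plus an optional smooth sinusoidal artifact of the given
    amplitude, with a random phase per marker and coordinate (emulating slow
    skin movement). Deterministic per seed; ``sigma=0`` with zero amplitude
    returns identical positions."""
    rng = np.random.default_rng(seed)
    S = markers.S.copy()
    S += sigma * rng.standard_normal(S.shape)
    if artifact_amplitude > 0.0:
        t = markers.time
        phase = rng.uniform(0, 2 * np.pi, size=S.shape[1:])
        S += artifact_amplitude * np.sin(
            2 * np.pi * artifact_freq_hz * t[:, None, None] + phase[None])
    return MarkerSet(markers.labels, S, markers.dt, markers.weights.copy(), markers.t0)


def make_trial(seed: int = 0, n_nodes: int = 120, dt: float = 0.01,
               sigma: float = 0.005, model: WalkingModel | None = None,
               speed: float = 1.25, stride_duration: float | None = None,
               amplitude_scale: float = 1.0, artifact_amplitude: float = 0.0,
               consistency_tol: float = 1e-9) -> SynthTrial:
    """Generate one certified synthetic stride.

    Builds kinematics and matching loads, evaluates the model markers, adds
    measurement noise, and *asserts* the consistency invariant: inverse
    dynamics of the clean trial must give residual force below
    ``consistency_tol`` times body weight (torque: times body weight times
    trunk length) at every interior node.
    """
    if model is None:
        model = default_model()
    traj = generate_kinematics(model, n_nodes, dt, stride_duration, speed,
                               amplitude_scale, seed)
    lam = support_schedule(n_nodes, dt, stride_duration)
    loads = consistent_loads_from_kinematics(model, traj, lam)

    frames = differentiate_frames(model, traj)
    res = run_inverse_dynamics(model, frames, loads)
    bw = model.body_weight
    f_ok = np.max(np.abs(res.F_res)) < consistency_tol * bw
    t_ok = np.max(np.abs(res.T_res)) < consistency_tol * bw * model.segment("trunk").length
    if not (f_ok and t_ok):
        raise AssertionError("synthetic trial failed its consistency certificate")

    clean = MarkerSet(model.marker_labels, frames.S, dt)
    noisy = add_marker_noise(clean, sigma, seed + 1,
                             artifact_amplitude=artifact_amplitude)
    return SynthTrial(model, traj, loads, clean, noisy, sigma, seed)
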