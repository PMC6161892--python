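"""Planar rigid linked-segment model of walking and its forward kinematics.

The concrete model is a seven-segment sagittal-plane chain — two feet, two
shanks, two thighs and one head-arms-trunk (HAT) segment — connected by pin
joints, with the two hips lumped into a single hip joint and the two shoulders
into a single shoulder point. Its configuration is described by nine
generalized coordinates: seven segment angles (measured counter-clockwise from
the +x walking direction) followed by the hip position::

    q = (q_foot_r, q_shank_r, q_thigh_r, q_foot_l, q_shank_l, q_thigh_l,
         q_trunk, x_hip, y_hip)

Segment axes run proximal (closer to the hip) to distal: thigh hip->knee,
shank knee->ankle, foot ankle->MTP, trunk hip->shoulder. All quantities SI,
y up, gravity (0, -g).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .preprocess import MarkerSet

__all__ = [
    "SegmentParams",
    "WalkingModel",
    "Trajectory",
    "KinematicsFrames",
    "SEGMENT_NAMES",
    "DOF_NAMES",
    "DEFAULT_MARKER_MAP",
    "default_anthropometric_table",
    "build_walking_model",
    "segment_lengths_from_markers",
    "forward_kinematics",
    "determinacy_counts",
]

SEGMENT_NAMES = ("foot_r", "shank_r", "thigh_r", "foot_l", "shank_l", "thigh_l", "trunk")
DOF_NAMES = ("q_foot_r", "q_shank_r", "q_thigh_r", "q_foot_l", "q_shank_l", "q_thigh_l",
             "q_trunk", "x_hip", "y_hip")

#: measured marker label -> (segment, fraction along the proximal->distal axis).
#: The single markers sit at the joint axes: fifth metatarsophalangeal joint,
#: lateral malleolus (ankle), lateral knee epicondyle, greater trochanter and
#: acromion, on both sides. Both trochanters map to the lumped hip point and
#: both acromions to the lumped shoulder point.
DEFAULT_MARKER_MAP: dict[str, tuple[str, float]] = {
    "mtp_r": ("foot_r", 1.0),
    "ankle_r": ("foot_r", 0.0),
    "knee_r": ("shank_r", 0.0),
    "troch_r": ("thigh_r", 0.0),
    "acr_r": ("trunk", 1.0),
    "mtp_l": ("foot_l", 1.0),
    "ankle_l": ("foot_l", 0.0),
    "knee_l": ("shank_l", 0.0),
    "troch_l": ("thigh_l", 0.0),
    "acr_l": ("trunk", 1.0),
}

_CONFIG_ERR = "anthropometric table is missing entry {0!r} (need mass_fraction, " \
    "com_fraction_proximal, gyration_fraction per segment)"


class ConfigurationError(ValueError):
    """Invalid model configuration (bad table entry, length, fraction...)."""


@dataclass(frozen=True)
class SegmentParams:
    """One rigid segment: mass (kg), length (m), COM position as a fraction of
    length from the proximal joint, and moment of inertia about the COM
    (kg m^2, axis perpendicular to the sagittal plane)."""

    name: str
    mass: float
    length: float
    com_fraction: float
    inertia_com: float

    def __post_init__(self) -> None:
        if self.mass <= 0 or self.length <= 0:
            raise ConfigurationError(f"segment {self.name!r}: mass and length must be positive")
        if not 0.0 <= self.com_fraction <= 1.0:
            raise ConfigurationError(f"segment {self.name!r}: com_fraction must lie in [0, 1]")
        if self.inertia_com < 0:
            raise ConfigurationError(f"segment {self.name!r}: inertia_com must be >= 0")


@dataclass
class WalkingModel:
    """The seven-segment, nine-DOF planar walking chain.

    ``segments`` are ordered as :data:`SEGMENT_NAMES`. ``marker_map`` places
    each measured marker label on a segment axis. Gravity defaults to
    (0, -9.81) m/s^2.
    """

    segments: tuple[SegmentParams, ...]
    marker_map: dict[str, tuple[str, float]]
    subject_mass: float
    gravity: np.ndarray = field(default_factory=lambda: np.array([0.0, -9.81]))

    def __post_init__(self) -> None:
        names = tuple(s.name for s in self.segments)
        if names != SEGMENT_NAMES:
            raise ConfigurationError(f"segments must be ordered {SEGMENT_NAMES}, got {names}")
        if self.subject_mass <= 0:
            raise ConfigurationError("subject mass must be positive")
        total = sum(s.mass for s in self.segments)
        if total > self.subject_mass * (1 + 1e-9):
            raise ConfigurationError(
                f"modelled segment mass {total:.3f} kg exceeds subject mass {self.subject_mass} kg")
        for label, (seg, frac) in self.marker_map.items():
            if seg not in SEGMENT_NAMES:
                raise ConfigurationError(f"marker {label!r} maps to unknown segment {seg!r}")
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError(f"marker {label!r}: fraction must lie in [0, 1]")
        self.gravity = np.asarray(self.gravity, dtype=float)

    # -- convenience views -------------------------------------------------
    @property
    def n_dof(self) -> int:
        return 9

    @property
    def marker_labels(self) -> tuple[str, ...]:
        return tuple(self.marker_map)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([s.length for s in self.segments])

    @property
    def masses(self) -> np.ndarray:
        return np.array([s.mass for s in self.segments])

    @property
    def com_fractions(self) -> np.ndarray:
        return np.array([s.com_fraction for s in self.segments])

    @property
    def inertias(self) -> np.ndarray:
        return np.array([s.inertia_com for s in self.segments])

    @property
    def body_weight(self) -> float:
        """Subject weight magnitude (N)."""
        return self.subject_mass * float(np.linalg.norm(self.gravity))

    def segment(self, name: str) -> SegmentParams:
        return self.segments[SEGMENT_NAMES.index(name)]


@dataclass
class Trajectory:
    """Generalized coordinates on a uniform time grid: Q has one row per node."""

    Q: np.ndarray
    dt: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q)
        if self.Q.ndim != 2:
            raise ValueError("Q must be a 2-D (N x n) array")
        if self.Q.shape[0] < 3:
            raise ValueError("a trajectory needs at least 3 time nodes")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_nodes(self) -> int:
        return self.Q.shape[0]

    @property
    def n_dof(self) -> int:
        return self.Q.shape[1]

    @property
    def time(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_nodes)

    def copy(self) -> "Trajectory":
        return Trajectory(self.Q.copy(), self.dt, self.t0)


@dataclass
class KinematicsFrames:
    """Cartesian kinematics derived from a trajectory.

    ``P`` maps joint names to (N, 2) position arrays, ``Z`` holds segment COM
    positions (N, 7, 2), ``S`` model marker positions (N, c, 2) in
    ``marker_map`` order. Velocity/acceleration arrays (``omega``, ``Zdd``,
    ``alpha``) keep the full length N but are NaN at the two boundary nodes,
    where the central-difference stencils are undefined.
    """

    P: dict[str, np.ndarray]
    Z: np.ndarray
    S: np.ndarray
    dt: float
    omega: np.ndarray | None = None
    Zdd: np.ndarray | None = None
    alpha: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return self.Z.shape[0]


def default_anthropometric_table() -> dict[str, dict[str, float]]:
    """The shipped segment-parameter table (editable: pass your own dict or
    YAML file to :func:`build_walking_model`)."""
    with resources.files("residyn.data").joinpath("winter.yaml").open() as fh:
        return yaml.safe_load(fh)


def build_walking_model(subject_mass: float, segment_lengths: dict[str, float],
                        anthro_table: dict[str, dict[str, float]] | None = None,
                        marker_map: dict[str, tuple[str, float]] | None = None,
                        g: float = 9.81) -> WalkingModel:
    """Assemble the walking model from subject mass, segment lengths and an
    anthropometric table.

    ``segment_lengths`` may use per-side keys (``foot_r`` ... ``trunk``) or
    symmetric keys (``foot``, ``shank``, ``thigh``, ``trunk``). Each segment
    gets ``mass = mass_fraction * subject_mass`` and
    ``inertia = mass * (gyration_fraction * length)**2``.
    """
    table = default_anthropometric_table() if anthro_table is None else anthro_table

    def length_of(seg: str) -> float:
        base = seg.rsplit("_", 1)[0] if seg != "trunk" else "trunk"
        if seg in segment_lengths:
            val = segment_lengths[seg]
        elif base in segment_lengths:
            val = segment_lengths[base]
        else:
            raise ConfigurationError(f"no length given for segment {seg!r}")
        if val <= 0:
            raise ConfigurationError(f"segment {seg!r}: length must be positive, got {val}")
        return float(val)

    segments = []
    for seg in SEGMENT_NAMES:
        base = "trunk" if seg == "trunk" else seg.rsplit("_", 1)[0]
        if base not in table:
            raise ConfigurationError(_CONFIG_ERR.format(base))
        entry = table[base]
        try:
            mf = float(entry["mass_fraction"])
            cf = float(entry["com_fraction_proximal"])
            kf = float(entry["gyration_fraction"])
        except (KeyError, TypeError) as exc:
            raise ConfigurationError(_CONFIG_ERR.format(base)) from exc
        if not (0 < mf < 1 and 0 <= cf < 1 and kf >= 0):
            raise ConfigurationError(f"anthropometric fractions for {base!r} out of range")
        L = length_of(seg)
        mass = mf * subject_mass
        segments.append(SegmentParams(seg, mass, L, cf, mass * (kf * L) ** 2))

    return WalkingModel(tuple(segments),
                        dict(DEFAULT_MARKER_MAP if marker_map is None else marker_map),
                        subject_mass, np.array([0.0, -g]))


def _lumped_points(markers: MarkerSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame lumped hip and shoulder estimates (bilateral marker means)."""
    hip = 0.5 * (markers.get("troch_r") + markers.get("troch_l"))
    shoulder = 0.5 * (markers.get("acr_r") + markers.get("acr_l"))
    return hip, shoulder


def segment_lengths_from_markers(markers: MarkerSet) -> dict[str, float]:
    """Segment lengths as time-averaged inter-marker distances.

    The lumped hip (mean of the trochanter markers) and shoulder (mean of the
    acromions) are formed per frame before distances are taken. Requires the
    standard label set (``mtp/ankle/knee/troch/acr`` per side). Raises
    ``KeyError`` naming any missing marker.
    """
    hip, shoulder = _lumped_points(markers)
    pairs = {
        "thigh_r": (hip, markers.get("knee_r")),
        "shank_r": (markers.get("knee_r"), markers.get("ankle_r")),
        "foot_r": (markers.get("ankle_r"), markers.get("mtp_r")),
        "thigh_l": (hip, markers.get("knee_l")),
        "shank_l": (markers.get("knee_l"), markers.get("ankle_l")),
        "foot_l": (markers.get("ankle_l"), markers.get("mtp_l")),
        "trunk": (hip, shoulder),
    }
    out = {}
    for seg, (a, b) in pairs.items():
        d = np.linalg.norm(b - a, axis=1)
        if np.any(~np.isfinite(d)):
            frame = int(np.flatnonzero(~np.isfinite(d))[0])
            raise ValueError(f"non-finite marker data for segment {seg!r} at frame {frame}")
        out[seg] = float(d.mean())
    return out


# segment index blocks used by the kinematic chain: per leg, thigh -> shank -> foot
_LEGS = {"right": (2, 1, 0), "left": (5, 4, 3)}
_JOINT_CHAIN = {"right": ("knee_r", "ankle_r", "mtp_r"), "left": ("knee_l", "ankle_l", "mtp_l")}


def forward_kinematics(model: WalkingModel, traj: Trajectory | np.ndarray) -> KinematicsFrames:
    """Joint, COM and model-marker positions from generalized coordinates.

    Purely per-frame trigonometry: the hip sits at ``(x_hip, y_hip)``; each
    joint lies one segment length further along ``(cos q, sin q)``; COMs and
    markers sit at their fractions along the same axes.
    """
    Q = traj.Q if isinstance(traj, Trajectory) else np.asarray(traj)
    dt = traj.dt if isinstance(traj, Trajectory) else 1.0
    if Q.ndim != 2 or Q.shape[1] != model.n_dof:
        raise ValueError(f"Q must be (N, {model.n_dof}), got {Q.shape}")
    ang = Q[:, :7]
    hip = Q[:, 7:9]
    u = np.stack([np.cos(ang), np.sin(ang)], axis=-1)          # (N, 7, 2)
    L = model.lengths

    P: dict[str, np.ndarray] = {"hip": hip}
    prox = np.empty_like(u)                                     # proximal joint per segment
    for side, (i_thigh, i_shank, i_foot) in _LEGS.items():
        knee, ankle, mtp = _JOINT_CHAIN[side]
        P[knee] = hip + L[i_thigh] * u[:, i_thigh]
        P[ankle] = P[knee] + L[i_shank] * u[:, i_shank]
        P[mtp] = P[ankle] + L[i_foot] * u[:, i_foot]
        prox[:, i_thigh] = hip
        prox[:, i_shank] = P[knee]
        prox[:, i_foot] = P[ankle]
    P["shoulder"] = hip + L[6] * u[:, 6]
    prox[:, 6] = hip

    Z = prox + (model.com_fractions[:, None] * L[:, None])[None, :, :] * u

    labels = model.marker_labels
    S = np.empty((Q.shape[0], len(labels), 2), dtype=u.dtype)
    for j, label in enumerate(labels):
        seg, frac = model.marker_map[label]
        k = SEGMENT_NAMES.index(seg)
        S[:, j] = prox[:, k] + frac * L[k] * u[:, k]

    return KinematicsFrames(P=P, Z=Z, S=S, dt=dt)


def determinacy_counts(n_dof: int, n_nodes: int) -> tuple[int, int]:
    """Equation/unknown bookkeeping for a planar chain of ``n`` pin-joined
    segments over ``N`` time nodes when external forces are fixed to the
    measurements: three Newton-Euler equations per segment per node versus
    ``2(n-1)`` joint force components, ``n-1`` joint torques and ``n`` segment
    angles per node. Returns ``(equations, unknowns) = (3 n N, (4 n - 3) N)``;
    the system balances only at ``n = 3`` and is underdetermined for ``n > 3``,
    which is what a whole-trajectory objective resolves."""
    return 3 * n_dof * n_nodes, (4 * n_dof - 3) * n_nodes
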