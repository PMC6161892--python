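"""File formats and run configuration.

Plain CSV with strict headers is the primary interchange format — the data
are simple planar time series and portability beats fidelity to lab formats.
All files are SI (m, N, s) with a mandatory header row and a uniform,
monotone ``time`` column. A minimal TRC-dialect importer is provided for
motion-capture exports (mm converted to m).
"""

from __future__ import annotations

from dataclasses import dataclass, fields as _dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .invdyn import InvDynResult
from .model import DOF_NAMES, Trajectory
from .preprocess import ExternalLoads, FootLoads, MarkerSet

__all__ = ["read_markers", "write_markers", "read_foot_loads", "write_foot_loads",
           "read_loads", "write_loads", "read_trajectory", "write_trajectory",
           "write_invdyn", "read_trc", "RunConfig"]

_TIME_TOL = 1e-9


def _check_time(t: np.ndarray, path) -> float:
    if len(t) < 2:
        raise ValueError(f"{path}: need at least two samples")
    dt = np.diff(t)
    if np.any(dt <= 0) or np.ptp(dt) > 1e-6 * dt[0]:
        raise ValueError(f"{path}: time column must be uniformly increasing")
    return float(dt.mean())


def _read_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise ValueError(f"{path}: missing mandatory 'time' column")
    return df


def read_markers(path) -> MarkerSet:
    """Read a marker CSV with columns ``time, <label>_x, <label>_y`` (m)."""
    df = _read_csv(path)
    dt = _check_time(df["time"].to_numpy(), path)
    labels = []
    for col in df.columns:
        if col.endswith("_x"):
            lb = col[:-2]
            if f"{lb}_y" not in df.columns:
                raise ValueError(f"{path}: marker {lb!r} has an _x column but no _y")
            labels.append(lb)
    if not labels:
        raise ValueError(f"{path}: no <label>_x/<label>_y marker columns found")
    S = np.stack([df[[f"{lb}_x", f"{lb}_y"]].to_numpy() for lb in labels], axis=1)
    return MarkerSet(tuple(labels), S, dt, t0=float(df["time"].iloc[0]))


def write_markers(markers: MarkerSet, path) -> None:
    data = {"time": markers.time}
    for j, lb in enumerate(markers.labels):
        data[f"{lb}_x"] = markers.S[:, j, 0]
        data[f"{lb}_y"] = markers.S[:, j, 1]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.9g")


def read_foot_loads(path) -> tuple[FootLoads, float, float]:
    """Read one foot's force CSV (``time, fx, fy, copx, copy`` — COP blank or
    NaN during swing). Returns (loads, dt, t0)."""
    df = _read_csv(path)
    for col in ("fx", "fy", "copx", "copy"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    dt = _check_time(df["time"].to_numpy(), path)
    F = df[["fx", "fy"]].to_numpy()
    cop = df[["copx", "copy"]].to_numpy()
    swing = (np.linalg.norm(F, axis=1) == 0.0) | np.isnan(cop[:, 0])
    F = np.where(swing[:, None], 0.0, F)
    cop[swing] = np.nan
    return FootLoads(F, cop, swing), dt, float(df["time"].iloc[0])


def write_foot_loads(foot: FootLoads, dt: float, path, t0: float = 0.0) -> None:
    n = foot.F.shape[0]
    pd.DataFrame({"time": t0 + dt * np.arange(n), "fx": foot.F[:, 0], "fy": foot.F[:, 1],
                  "copx": foot.cop[:, 0], "copy": foot.cop[:, 1]}
                 ).to_csv(path, index=False, float_format="%.9g")


def read_loads(right_path, left_path) -> ExternalLoads:
    right, dt_r, t0 = read_foot_loads(right_path)
    left, dt_l, _ = read_foot_loads(left_path)
    if abs(dt_r - dt_l) > _TIME_TOL:
        raise ValueError("right/left force files disagree on the sampling interval")
    return ExternalLoads(right, left, dt_r, t0)


def write_loads(loads: ExternalLoads, right_path, left_path) -> None:
    write_foot_loads(loads.right, loads.dt, right_path, loads.t0)
    write_foot_loads(loads.left, loads.dt, left_path, loads.t0)


def read_trajectory(path) -> Trajectory:
    df = _read_csv(path)
    missing = [c for c in DOF_NAMES if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing coordinate column(s) {missing}")
    dt = _check_time(df["time"].to_numpy(), path)
    return Trajectory(df[list(DOF_NAMES)].to_numpy(), dt, float(df["time"].iloc[0]))


def write_trajectory(traj: Trajectory, path) -> None:
    data = {"time": traj.time}
    data.update({name: traj.Q[:, k] for k, name in enumerate(DOF_NAMES)})
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.12g")


def write_invdyn(result: InvDynResult, path, subject_mass: float | None = None,
                 g: float = 9.81) -> None:
    """Write per-node joint loads and residuals; residual force also in %BW
    when the subject mass is given."""
    n = result.n_nodes
    data = {"time": result.dt * (result.node_offset + np.arange(n))}
    for joint, T in result.joint_torques.items():
        data[f"T_{joint}"] = T
    for joint, F in result.joint_forces.items():
        data[f"F_{joint}_x"] = F[:, 0]
        data[f"F_{joint}_y"] = F[:, 1]
    data["F_res_x"] = result.F_res[:, 0]
    data["F_res_y"] = result.F_res[:, 1]
    data["T_res"] = result.T_res
    if subject_mass is not None:
        bw = subject_mass * g
        data["F_res_x_pct_bw"] = 100.0 * result.F_res[:, 0] / bw
        data["F_res_y_pct_bw"] = 100.0 * result.F_res[:, 1] / bw
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.9g")


def read_trc(path, axes: tuple[int, int] = (0, 1)) -> MarkerSet:
    """Minimal TRC-dialect import.

    Reads the standard header (data rate, units, marker names) and the frame
    table, keeps the two requested axes of each marker (default X, Y) as the
    sagittal plane, and converts mm to m when the file declares mm.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 6 or not lines[0].startswith("PathFileType"):
        raise ValueError(f"{path}: not a TRC file (missing PathFileType header)")
    meta_keys = lines[1].split("\t")
    meta_vals = lines[2].split("\t")
    meta = dict(zip(meta_keys, meta_vals))
    units = meta.get("Units", "mm").strip()
    scale = {"mm": 1e-3, "m": 1.0}.get(units)
    if scale is None:
        raise ValueError(f"{path}: unsupported units {units!r}")
    rate = float(meta.get("DataRate", meta.get("CameraRate", "0")))
    if rate <= 0:
        raise ValueError(f"{path}: missing DataRate")
    header = lines[3].split("\t")
    labels = [h.strip() for h in header[2:] if h.strip()]
    rows = []
    for line in lines[5:]:
        if not line.strip():
            continue
        rows.append([float(v) if v.strip() else np.nan for v in line.split("\t")])
    arr = np.asarray(rows)
    if arr.shape[1] < 2 + 3 * len(labels):
        raise ValueError(f"{path}: frame rows shorter than 3 columns per marker")
    S = np.empty((arr.shape[0], len(labels), 2))
    for j in range(len(labels)):
        block = arr[:, 2 + 3 * j : 2 + 3 * j + 3]
        S[:, j] = scale * block[:, list(axes)]
    return MarkerSet(tuple(labels), S, 1.0 / rate, t0=float(arr[0, 1]))


@dataclass
class RunConfig:
    """Configuration of a full analysis run (YAML-serializable).

    Filter cutoffs follow the standard conditioning: 10 Hz for kinematics,
    20 Hz for ground reaction forces, both zero-lag 4th order; the contact
    threshold is expressed as a fraction of body weight.
    """

    subject_mass: float = 66.1
    marker_cutoff_hz: float = 10.0
    force_cutoff_hz: float = 20.0
    filter_order: int = 4
    contact_threshold_bw: float = 0.01
    residual_point: str = "shoulder"
    constraint_tol: float = 1e-6
    optimality_tol: float = 1e-6
    max_iter: int = 500
    seed: int = 0
    anthro_table_path: str | None = None

    def __post_init__(self) -> None:
        for name in ("subject_mass", "marker_cutoff_hz", "force_cutoff_hz",
                     "filter_order", "contact_threshold_bw", "constraint_tol",
                     "optimality_tol", "max_iter"):
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name!r} must be positive")
        if self.residual_point not in ("shoulder", "trunk_com"):
            raise ValueError("residual_point must be 'shoulder' or 'trunk_com'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in _dc_fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(
            {f.name: getattr(self, f.name) for f in _dc_fields(self)},
            sort_keys=False))
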