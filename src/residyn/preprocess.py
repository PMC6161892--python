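"""Measurement conditioning: zero-lag filtering, downsampling, COP, stride selection.

The containers defined here (:class:`MarkerSet`, :class:`ExternalLoads`) hold the
*measured* inputs of an analysis: skin-marker trajectories and per-foot ground
reaction forces with their points of application (centers of pressure, COP).
External loads are never modified downstream — the whole point of the
residual-elimination algorithm is to adjust kinematics only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _signal

__all__ = [
    "MarkerSet",
    "FootLoads",
    "ExternalLoads",
    "zero_lag_lowpass",
    "downsample",
    "cop_from_plate",
    "detect_strides",
]


@dataclass
class MarkerSet:
    """Measured marker positions on a uniform time grid.

    Parameters
    ----------
    labels : sequence of str
        Marker names, one per column of ``S``.
    S : ndarray, shape (N, c, 2)
        Sagittal-plane positions in metres; ``S[i, j]`` is marker ``j`` at node ``i``.
    dt : float
        Sampling interval in seconds.
    weights : ndarray, shape (c,), optional
        Non-negative per-marker weights for the mismatch objective (default all 1,
        the value used in the walking application).
    t0 : float
        Time of the first node.
    """

    labels: tuple[str, ...]
    S: np.ndarray
    dt: float
    weights: np.ndarray | None = None
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.S = np.asarray(self.S, dtype=float)
        if self.S.ndim != 3 or self.S.shape[2] != 2:
            raise ValueError(f"S must have shape (N, c, 2), got {self.S.shape}")
        if self.S.shape[1] != len(self.labels):
            raise ValueError("number of labels does not match S")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.weights is None:
            self.weights = np.ones(len(self.labels))
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.labels),) or np.any(self.weights < 0):
            raise ValueError("weights must be one non-negative value per marker")

    @property
    def n_frames(self) -> int:
        return self.S.shape[0]

    @property
    def time(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_frames)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"marker {label!r} not present (have {self.labels})") from None

    def get(self, label: str) -> np.ndarray:
        """Positions of one marker, shape (N, 2)."""
        return self.S[:, self.index(label), :]

    def window(self, start: int, stop: int) -> "MarkerSet":
        """Extract frames ``start..stop`` (inclusive)."""
        return replace(self, S=self.S[start : stop + 1].copy(),
                       t0=self.t0 + start * self.dt)


@dataclass
class FootLoads:
    """One foot's external load record.

    ``F`` is the ground reaction force (N), ``cop`` its point of application on
    the walking surface (m, NaN while the foot is in swing), ``swing`` the
    per-frame swing flag. During swing frames the force is exactly zero.
    """

    F: np.ndarray
    cop: np.ndarray
    swing: np.ndarray

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        self.cop = np.asarray(self.cop, dtype=float)
        self.swing = np.asarray(self.swing, dtype=bool)
        n = self.F.shape[0]
        if self.F.shape != (n, 2) or self.cop.shape != (n, 2) or self.swing.shape != (n,):
            raise ValueError("inconsistent foot-load array shapes")
        if np.any(self.F[self.swing] != 0.0):
            raise ValueError("swing frames must carry exactly zero force")


@dataclass
class ExternalLoads:
    """Per-foot external forces and centers of pressure on a uniform grid."""

    right: FootLoads
    left: FootLoads
    dt: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.right.F.shape[0] != self.left.F.shape[0]:
            raise ValueError("right/left records differ in length")

    @property
    def n_frames(self) -> int:
        return self.right.F.shape[0]

    @property
    def feet(self) -> dict[str, FootLoads]:
        return {"right": self.right, "left": self.left}

    def total_force(self) -> np.ndarray:
        return self.right.F + self.left.F

    def window(self, start: int, stop: int) -> "ExternalLoads":
        """Extract frames ``start..stop`` (inclusive)."""

        def cut(f: FootLoads) -> FootLoads:
            return FootLoads(f.F[start : stop + 1].copy(), f.cop[start : stop + 1].copy(),
                             f.swing[start : stop + 1].copy())

        return ExternalLoads(cut(self.right), cut(self.left), self.dt,
                             t0=self.t0 + start * self.dt)

    def copy(self) -> "ExternalLoads":
        return self.window(0, self.n_frames - 1)


def zero_lag_lowpass(series: np.ndarray, cutoff_hz: float, fs_hz: float,
                     order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass filter (forward-backward application).

    The filter is applied along the first axis. The forward-backward pass
    cancels the phase delay and doubles the effective order, the standard
    conditioning for kinematic and force-plate series.

    Raises ``ValueError`` if the series is shorter than the filter's padding
    requirement or the cutoff is not below the Nyquist frequency.
    """
    x = np.asarray(series, dtype=float)
    if fs_hz <= 2 * cutoff_hz:
        raise ValueError(f"sampling rate {fs_hz} Hz must exceed twice the cutoff {cutoff_hz} Hz")
    b, a = _signal.butter(order, cutoff_hz, btype="low", fs=fs_hz)
    padlen = 3 * (max(len(a), len(b)) - 1)
    if x.shape[0] <= padlen:
        raise ValueError(f"series of length {x.shape[0]} too short for filtering "
                         f"(needs > {padlen} samples)")
    return _signal.filtfilt(b, a, x, axis=0)


def downsample(series: np.ndarray, fs_high: float, target_fs: float) -> np.ndarray:
    """Decimate an already low-pass-filtered series by keeping every k-th sample.

    ``fs_high`` must be an integer multiple of ``target_fs`` (e.g. force-plate
    data at 200 Hz reduced to the 100 Hz motion-capture rate).
    """
    ratio = fs_high / target_fs
    k = int(round(ratio))
    if abs(ratio - k) > 1e-9 or k < 1:
        raise ValueError(f"{fs_high} Hz is not an integer multiple of {target_fs} Hz")
    return np.asarray(series)[::k]


def cop_from_plate(Fx: np.ndarray, Fy: np.ndarray, Mz: np.ndarray,
                   surface_height: float = 0.0, *,
                   threshold: float = 10.0) -> tuple[np.ndarray, np.ndarray]:
    """Center of pressure from planar force-plate channels.

    The plate reports the force components ``Fx`` (along the walking direction),
    ``Fy`` (vertical) and the free moment ``Mz`` about the plate origin. Moment
    balance about the origin for a force applied at ``(x, h)`` on the walking
    surface of height ``h`` gives ``Mz = x*Fy - h*Fx``, hence::

        x_cop = (Mz + h*Fx) / Fy

    Frames with ``|Fy|`` below ``threshold`` (N) are flagged swing: their COP is
    NaN and is never divided through, so no spurious values can propagate into
    the dynamics.

    Returns
    -------
    cop : ndarray, shape (N, 2)
    swing : ndarray of bool, shape (N,)
    """
    Fx = np.asarray(Fx, dtype=float)
    Fy = np.asarray(Fy, dtype=float)
    Mz = np.asarray(Mz, dtype=float)
    swing = np.abs(Fy) < threshold
    x = np.full(Fy.shape, np.nan)
    np.divide(Mz + surface_height * Fx, Fy, out=x, where=~swing)
    cop = np.stack([x, np.full_like(x, surface_height)], axis=-1)
    cop[swing] = np.nan
    return cop, swing


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True-runs of a boolean mask as (start, stop) inclusive pairs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    stops = np.concatenate([idx[breaks], [idx[-1]]])
    return list(zip(starts.tolist(), stops.tolist()))


def detect_strides(loads: ExternalLoads, threshold: float, *,
                   min_swing_samples: int = 3) -> list[tuple[int, int]]:
    """Segment a load record into strides bounded by right-foot toe-offs.

    A toe-off is the first sample of a below-threshold run of the right foot's
    force magnitude; a stride spans consecutive toe-offs (both bounding samples
    included, so re-applying this function to an extracted stride returns the
    same window). A stride is kept only if *both* feet show a contiguous swing
    interval of at least ``min_swing_samples`` inside it — i.e. two distinct
    swing phases with near-zero force.

    Returns a (possibly empty) list of (start, stop) inclusive index pairs.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    fmag_r = np.linalg.norm(loads.right.F, axis=1)
    fmag_l = np.linalg.norm(loads.left.F, axis=1)
    below_r = fmag_r < threshold
    toe_offs = [start for start, _ in _runs(below_r)]
    if len(toe_offs) < 2:
        warnings.warn("no complete stride found (need two right toe-offs)")
        return []
    windows = []
    for start, stop in zip(toe_offs[:-1], toe_offs[1:]):
        ok = True
        for below in (below_r, below_l := fmag_l < threshold):
            runs = [r for r in _runs(below[start : stop + 1])
                    if r[1] - r[0] + 1 >= min_swing_samples]
            if not runs:
                ok = False
        if ok:
            windows.append((start, stop))
    return windows
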