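"""Whole-trajectory constrained optimization that removes residual loads.

Given measured markers S' and measured external loads, find the trajectory Q
(all nine generalized coordinates at all N time nodes, 9N unknowns) that
minimizes the weighted squared marker mismatch::

    J(Q) = sum_i sum_j w_j | s_j(t_i) - s'_j(t_i) |^2

subject to zero residual force and torque at every interior time node. The
external loads are parameters, never decision variables: only the kinematics
move. For a chain with more than three degrees of freedom the constraint
system is underdetermined, so the objective selects the unique best-fit
consistent kinematics.

The default backend is an equality-constrained Gauss-Newton SQP written for
this problem's structure: the objective is a small-residual least-squares
with an analytic, node-block-diagonal Jacobian, and each constraint node
touches only trajectory nodes i-1, i, i+1, so the constraint Jacobian is
banded and is obtained exactly (complex-step) from 27 structured evaluations
regardless of N. Each iteration solves one sparse KKT system. A generic
``scipy.optimize`` trust-constr backend is available for cross-checking.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .invdyn import run_inverse_dynamics
from .kinematics import central_first_difference, central_second_difference
from .model import (SEGMENT_NAMES, KinematicsFrames, Trajectory, WalkingModel,
                    forward_kinematics)
from .preprocess import ExternalLoads, MarkerSet

__all__ = ["SolverOptions", "OptProblem", "OptResult", "initial_guess_from_markers",
           "objective_J", "constraint_vector", "solve"]


# --------------------------------------------------------------------------
# initial guess
# --------------------------------------------------------------------------

# model point -> (segment, fraction) aliases that identify it in a marker map
_POINT_ALIASES = {
    "hip": {("thigh_r", 0.0), ("thigh_l", 0.0), ("trunk", 0.0)},
    "shoulder": {("trunk", 1.0)},
    "knee_r": {("shank_r", 0.0), ("thigh_r", 1.0)},
    "ankle_r": {("foot_r", 0.0), ("shank_r", 1.0)},
    "mtp_r": {("foot_r", 1.0)},
    "knee_l": {("shank_l", 0.0), ("thigh_l", 1.0)},
    "ankle_l": {("foot_l", 0.0), ("shank_l", 1.0)},
    "mtp_l": {("foot_l", 1.0)},
}


def _estimated_points(model: WalkingModel, measured: MarkerSet) -> dict[str, np.ndarray]:
    """Per-frame estimates of the chain's joint points from measured markers.

    Labels mapping to the same model point (the two trochanters at the lumped
    hip, the two acromions at the lumped shoulder) are averaged frame-wise.
    """
    points: dict[str, list[np.ndarray]] = {}
    for label, (seg, frac) in model.marker_map.items():
        for point, aliases in _POINT_ALIASES.items():
            if any(seg == s and abs(frac - f) < 1e-12 for s, f in aliases):
                points.setdefault(point, []).append(measured.get(label))
                break
    missing = [p for p in _POINT_ALIASES if p not in points]
    if missing:
        raise ValueError(f"marker set does not determine model point(s) {missing}")
    return {p: np.mean(arrs, axis=0) for p, arrs in points.items()}


def initial_guess_from_markers(model: WalkingModel, measured: MarkerSet) -> Trajectory:
    """Trajectory estimated directly from measured markers.

    Hip coordinates are the mean of the two trochanter markers; each segment
    angle is the ``atan2`` of its distal minus proximal estimated point,
    unwrapped over time. On noise-free markers generated by the model's own
    forward kinematics this inverts exactly.
    """
    pts = _estimated_points(model, measured)
    chains = {"foot_r": ("ankle_r", "mtp_r"), "shank_r": ("knee_r", "ankle_r"),
              "thigh_r": ("hip", "knee_r"), "foot_l": ("ankle_l", "mtp_l"),
              "shank_l": ("knee_l", "ankle_l"), "thigh_l": ("hip", "knee_l"),
              "trunk": ("hip", "shoulder")}
    N = measured.n_frames
    Q = np.empty((N, model.n_dof))
    for k, seg in enumerate(SEGMENT_NAMES):
        a, b = chains[seg]
        d = pts[b] - pts[a]
        Q[:, k] = np.unwrap(np.arctan2(d[:, 1], d[:, 0]))
    Q[:, 7:9] = pts["hip"]
    return Trajectory(Q, measured.dt, measured.t0)


# --------------------------------------------------------------------------
# objective
# --------------------------------------------------------------------------

def objective_J(Q: Trajectory | np.ndarray, model: WalkingModel,
                measured: MarkerSet) -> float:
    """Weighted squared marker mismatch summed over all nodes and markers (m^2)."""
    frames = forward_kinematics(model, Q if isinstance(Q, np.ndarray) else Q.Q)
    diff = frames.S - measured.S
    return float(np.sum(measured.weights[None, :, None] * np.abs(diff) ** 2))


class _MarkerResiduals:
    """Weighted marker residual vector and its sparse analytic Jacobian.

    The residual of marker j at node i depends only on that node's nine
    coordinates, through the chain hip -> ... -> segment: the derivative with
    respect to an ancestor angle q_d is ``c * (-sin q_d, cos q_d)`` with c the
    (partial) length the angle carries, and the hip derivative is the
    identity. The Jacobian is therefore block-diagonal over nodes with an
    identical sparsity block, assembled once.
    """

    _CHAINS = {"foot_r": (2, 1, 0), "shank_r": (2, 1), "thigh_r": (2,),
               "foot_l": (5, 4, 3), "shank_l": (5, 4), "thigh_l": (5,),
               "trunk": (6,)}

    def __init__(self, model: WalkingModel, measured: MarkerSet):
        self.model = model
        self.measured = measured
        self.N = measured.n_frames
        self.labels = model.marker_labels
        if set(self.labels) - set(measured.labels):
            raise ValueError("measured marker set lacks labels "
                             f"{set(self.labels) - set(measured.labels)}")
        self._meas_idx = [measured.index(lb) for lb in self.labels]
        self.c = len(self.labels)
        self.sqw = np.sqrt(np.array([measured.weights[i] for i in self._meas_idx]))
        L = model.lengths
        # structural entries: (marker j, angle dof d, length coefficient)
        self._angle_terms: list[tuple[int, int, float]] = []
        for j, lb in enumerate(self.labels):
            seg, frac = model.marker_map[lb]
            chain = self._CHAINS[seg]
            for d in chain[:-1]:
                self._angle_terms.append((j, d, L[d]))
            d_last = chain[-1]
            if frac != 0.0:
                self._angle_terms.append((j, d_last, frac * L[d_last]))
        # per-node COO pattern (rows within 2c, cols within 9)
        rows, cols, self._coefs, self._kinds = [], [], [], []
        for j, d, coef in self._angle_terms:
            for axis in (0, 1):
                rows.append(2 * j + axis)
                cols.append(d)
                self._coefs.append(coef * self.sqw[j])
                self._kinds.append(axis)          # 0: -sin, 1: cos
        for j in range(self.c):
            for axis in (0, 1):
                rows.append(2 * j + axis)
                cols.append(7 + axis)
                self._coefs.append(self.sqw[j])
                self._kinds.append(2)             # constant 1
        self._rows = np.asarray(rows)
        self._cols = np.asarray(cols)
        self._coefs = np.asarray(self._coefs)
        self._kinds = np.asarray(self._kinds)
        # global indices for the block-diagonal assembly
        nnz = len(rows)
        node = np.arange(self.N)
        self._grows = (node[:, None] * 2 * self.c + self._rows[None, :]).ravel()
        self._gcols = (node[:, None] * 9 + self._cols[None, :]).ravel()
        self._Smeas = measured.S[:, self._meas_idx, :]

    def residuals(self, Q: np.ndarray) -> np.ndarray:
        S = forward_kinematics(self.model, Q).S
        r = (self.sqw[None, :, None] * (S - self._Smeas))
        return r.reshape(-1)

    def jacobian(self, Q: np.ndarray) -> sp.csr_matrix:
        ang = Q[:, :7]
        sin, cos = np.sin(ang), np.cos(ang)
        data = np.empty((self.N, len(self._rows)))
        is_sin = self._kinds == 0
        is_cos = self._kinds == 1
        is_one = self._kinds == 2
        data[:, is_sin] = -sin[:, self._cols[is_sin]] * self._coefs[is_sin]
        data[:, is_cos] = cos[:, self._cols[is_cos]] * self._coefs[is_cos]
        data[:, is_one] = self._coefs[is_one]
        return sp.csr_matrix((data.ravel(), (self._grows, self._gcols)),
                             shape=(self.N * 2 * self.c, self.N * 9))


# --------------------------------------------------------------------------
# constraints
# --------------------------------------------------------------------------

def _frames_from_Q(model: WalkingModel, Q: np.ndarray, dt: float) -> KinematicsFrames:
    frames = forward_kinematics(model, Q)
    frames.dt = dt
    frames.Zdd = central_second_difference(frames.Z, dt)
    frames.alpha = central_second_difference(Q[:, :7], dt)
    frames.omega = central_first_difference(Q[:, :7], dt)
    return frames


def constraint_vector(Q: np.ndarray | Trajectory, model: WalkingModel,
                      loads: ExternalLoads, dt: float | None = None,
                      sigma_F: float | None = None, sigma_T: float | None = None,
                      residual_point: str = "shoulder") -> np.ndarray:
    """Scaled residual force/torque constraints, length ``3 (N - 2)``.

    Per interior node: ``(F_res_x / sF, F_res_y / sF, T_res / sT)`` with
    ``sF`` the body weight and ``sT`` body weight times trunk length, so all
    entries are dimensionless and of comparable magnitude.
    """
    if isinstance(Q, Trajectory):
        dt = Q.dt
        Q = Q.Q
    if dt is None:
        raise ValueError("dt is required when Q is a bare array")
    sF = model.body_weight if sigma_F is None else sigma_F
    sT = sF * model.segment("trunk").length if sigma_T is None else sigma_T
    frames = _frames_from_Q(model, Q, dt)
    res = run_inverse_dynamics(model, frames, loads, residual_point)
    out = np.empty((res.F_res.shape[0], 3), dtype=res.F_res.dtype)
    out[:, 0] = res.F_res[:, 0] / sF
    out[:, 1] = res.F_res[:, 1] / sF
    out[:, 2] = res.T_res / sT
    return out.reshape(-1)


def _banded_constraint_jacobian(confun, x: np.ndarray, N: int, n_dof: int,
                                method: str = "cs") -> sp.csr_matrix:
    """Jacobian of a banded constraint vector by structured differentiation.

    The constraint block of interior node i depends only on trajectory nodes
    i-1, i, i+1, so perturbing every third node simultaneously (per degree of
    freedom) yields unambiguous columns: 3 * n_dof evaluations total. With
    ``method="cs"`` (complex step) the entries are exact to machine precision;
    ``"2-point"`` falls back to forward differences.
    """
    M = 3 * (N - 2)
    c0 = confun(x) if method != "cs" else None
    blocks = np.arange(N - 2)                     # constraint block j <-> node j+1
    rows_all, cols_all, data_all = [], [], []
    row_idx = (3 * blocks[:, None] + np.arange(3)[None, :]).ravel()
    for d in range(n_dof):
        for r in range(3):
            nodes = np.arange(N)[np.arange(N) % 3 == r]
            cols = nodes * n_dof + d
            if method == "cs":
                h = 1e-100
                xp = x.astype(complex)
                xp[cols] += 1j * h
                dc = np.imag(confun(xp)) / h
            else:
                h = 1e-7
                xp = x.copy()
                xp[cols] += h
                dc = (confun(xp) - c0) / h
            # block j touches nodes j, j+1, j+2; exactly one is ≡ r (mod 3)
            touched = blocks + (r - blocks) % 3
            col_of_block = touched * n_dof + d
            rows_all.append(row_idx)
            cols_all.append(np.repeat(col_of_block, 3))
            data_all.append(dc)
    A = sp.csr_matrix((np.concatenate(data_all),
                       (np.concatenate(rows_all), np.concatenate(cols_all))),
                      shape=(M, N * n_dof))
    A.sum_duplicates()
    return A


# --------------------------------------------------------------------------
# problem / result containers
# --------------------------------------------------------------------------

@dataclass
class SolverOptions:
    """Tolerances and controls for :func:`solve`.

    ``constraint_tol`` bounds the maximum scaled residual entry at the
    solution; ``optimality_tol`` the first-order (KKT stationarity) measure;
    ``step_tol`` the infinity-norm of the accepted step. All dimensionless /
    SI-scaled. ``fd_method`` selects the constraint-Jacobian scheme.
    """

    constraint_tol: float = 1e-6
    optimality_tol: float = 1e-6
    step_tol: float = 1e-10
    max_iter: int = 500
    method: str = "sqp"               # "sqp" | "trust-constr"
    fd_method: str = "cs"             # "cs" | "2-point"
    sigma_F: float | None = None
    sigma_T: float | None = None
    residual_point: str = "shoulder"
    regularization: float = 1e-10
    verbose: bool = False


@dataclass
class OptProblem:
    """A residual-elimination problem: model, measured markers, fixed loads,
    initial trajectory and solver options."""

    model: WalkingModel
    measured: MarkerSet
    loads: ExternalLoads
    Q0: Trajectory
    options: SolverOptions = field(default_factory=SolverOptions)

    def __post_init__(self) -> None:
        if self.Q0.n_dof != self.model.n_dof:
            raise ValueError("initial guess DOF count does not match the model")
        if self.Q0.n_nodes != self.measured.n_frames or \
                self.Q0.n_nodes != self.loads.n_frames:
            raise ValueError("markers, loads and initial guess must share the time grid")
        if abs(self.measured.dt - self.Q0.dt) > 1e-12 or abs(self.loads.dt - self.Q0.dt) > 1e-12:
            raise ValueError("markers, loads and initial guess must share dt")


@dataclass
class OptResult:
    """Outcome of :func:`solve`: optimized trajectory, final objective (m^2),
    maximum scaled constraint violation, convergence flag and an iteration log."""

    Q_opt: Trajectory
    J: float
    max_constraint_violation: float
    converged: bool
    iterations: int
    log: list[dict] = field(default_factory=list)
    J_initial: float = float("nan")
    wall_time_s: float = float("nan")
    method: str = "sqp"


# --------------------------------------------------------------------------
# solver
# --------------------------------------------------------------------------

def solve(problem: OptProblem) -> OptResult:
    """Minimize the marker mismatch subject to zero residuals at all interior
    nodes. Deterministic given the initial guess and options. Non-convergence
    is reported in the result (``converged=False``), never raised."""
    opts = problem.options
    if opts.method == "trust-constr":
        return _solve_trust_constr(problem)
    if opts.method != "sqp":
        raise ValueError(f"unknown method {opts.method!r}")
    return _solve_sqp(problem)


def _solve_sqp(problem: OptProblem) -> OptResult:
    t_start = time.perf_counter()
    model, measured, loads = problem.model, problem.measured, problem.loads
    opts = problem.options
    N = problem.Q0.n_nodes
    n = model.n_dof
    dt = problem.Q0.dt
    res = _MarkerResiduals(model, measured)

    def confun(x):
        return constraint_vector(x.reshape(N, n), model, loads, dt,
                                 opts.sigma_F, opts.sigma_T, opts.residual_point)

    x = problem.Q0.Q.reshape(-1).astype(float).copy()
    r = res.residuals(x.reshape(N, n))
    J = float(r @ r)
    J0 = J
    c = confun(x)
    rho = 1.0
    log: list[dict] = []
    converged = False
    it = 0
    for it in range(1, opts.max_iter + 1):
        Jr = res.jacobian(x.reshape(N, n))
        A = _banded_constraint_jacobian(confun, x, N, n, opts.fd_method)
        g = 2.0 * (Jr.T @ r)
        H = (2.0 * (Jr.T @ Jr)).tolil()
        reg = opts.regularization * max(1.0, J)
        H.setdiag(H.diagonal() + reg)
        K = sp.bmat([[H.tocsc(), A.T], [A, None]], format="csc")
        rhs = np.concatenate([-g, -c])
        sol = splu(K).solve(rhs)
        dx, lam = sol[: x.size], sol[x.size:]

        viol = float(np.max(np.abs(c)))
        stat = float(np.max(np.abs(g + A.T @ lam)))
        if viol <= opts.constraint_tol and \
                (stat <= opts.optimality_tol * max(1.0, float(np.max(np.abs(g))))
                 or float(np.max(np.abs(dx))) <= opts.step_tol):
            converged = True
            log.append({"iter": it, "J": J, "viol": viol, "stat": stat, "alpha": 0.0})
            break

        # merit line search (l1 penalty)
        rho = max(rho, 2.0 * float(np.max(np.abs(lam))) if lam.size else rho)
        phi0 = J + rho * float(np.sum(np.abs(c)))
        D = float(g @ dx) - rho * float(np.sum(np.abs(c)))
        alpha = 1.0
        for _ in range(40):
            x_new = x + alpha * dx
            r_new = res.residuals(x_new.reshape(N, n))
            J_new = float(r_new @ r_new)
            c_new = confun(x_new)
            phi = J_new + rho * float(np.sum(np.abs(c_new)))
            if phi <= phi0 + 1e-4 * alpha * D or alpha < 1e-8:
                break
            alpha *= 0.5
        x, r, J, c = x_new, r_new, J_new, c_new
        log.append({"iter": it, "J": J, "viol": float(np.max(np.abs(c))),
                    "stat": stat, "alpha": alpha})
        if opts.verbose:
            print(f"  it {it:3d}  J={J:.6e}  viol={log[-1]['viol']:.3e}  alpha={alpha:g}")

    return OptResult(Q_opt=Trajectory(x.reshape(N, n), dt, problem.Q0.t0),
                     J=J, max_constraint_violation=float(np.max(np.abs(c))),
                     converged=converged, iterations=it, log=log, J_initial=J0,
                     wall_time_s=time.perf_counter() - t_start, method="sqp")


def _solve_trust_constr(problem: OptProblem) -> OptResult:
    from scipy.optimize import NonlinearConstraint, minimize

    t_start = time.perf_counter()
    model, measured, loads = problem.model, problem.measured, problem.loads
    opts = problem.options
    N, n, dt = problem.Q0.n_nodes, model.n_dof, problem.Q0.dt
    res = _MarkerResiduals(model, measured)

    def confun(x):
        return constraint_vector(x.reshape(N, n), model, loads, dt,
                                 opts.sigma_F, opts.sigma_T, opts.residual_point)

    def fun(x):
        r = res.residuals(x.reshape(N, n))
        return float(r @ r)

    def grad(x):
        r = res.residuals(x.reshape(N, n))
        return 2.0 * (res.jacobian(x.reshape(N, n)).T @ r)

    nlc = NonlinearConstraint(
        confun, 0.0, 0.0,
        jac=lambda x: _banded_constraint_jacobian(confun, x, N, n, opts.fd_method))
    x0 = problem.Q0.Q.reshape(-1).astype(float)
    out = minimize(fun, x0, jac=grad, method="trust-constr", constraints=[nlc],
                   options={"maxiter": opts.max_iter, "gtol": opts.optimality_tol,
                            "xtol": opts.step_tol, "verbose": 3 if opts.verbose else 0})
    c = confun(out.x)
    viol = float(np.max(np.abs(c)))
    return OptResult(Q_opt=Trajectory(out.x.reshape(N, n), dt, problem.Q0.t0),
                     J=float(out.fun), max_constraint_violation=viol,
                     converged=bool(out.success or viol <= opts.constraint_tol),
                     iterations=int(out.nit), J_initial=fun(x0),
                     log=[{"message": out.message}],
                     wall_time_s=time.perf_counter() - t_start, method="trust-constr")
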