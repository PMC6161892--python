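"""Independent forward-dynamics oracle: a planar two-link pendulum.

The equations of motion are derived symbolically (Lagrangian in absolute link
angles, prescribed pivot and inter-link torques), integrated to high accuracy,
and the sampled motion is then pushed through the package's central-difference
plus Newton-Euler recursion. Recovered torques must match the prescribed ones
with an O(dt^2) error.
"""

import numpy as np
import sympy as sp
from scipy.integrate import solve_ivp

from residyn import central_second_difference, segment_solve
from residyn.model import SegmentParams

PARAMS = dict(m1=3.0, m2=2.0, L1=0.5, L2=0.4, c1=0.45, c2=0.4, I1=0.06, I2=0.03, g=9.81)


def tau1_fn(t):
    return 1.5 * np.sin(3 * t) + 0.4


def tau2_fn(t):
    return 0.8 * np.cos(2 * t)


def _derive_forward_dynamics():
    t = sp.symbols("t")
    th1, th2 = sp.Function("th1")(t), sp.Function("th2")(t)
    m1, m2, L1, L2, c1, c2, I1, I2, g = sp.symbols(
        "m1 m2 L1 L2 c1 c2 I1 I2 g", positive=True)
    p1 = sp.Matrix([c1 * L1 * sp.cos(th1), c1 * L1 * sp.sin(th1)])
    p2 = sp.Matrix([L1 * sp.cos(th1) + c2 * L2 * sp.cos(th2),
                    L1 * sp.sin(th1) + c2 * L2 * sp.sin(th2)])
    v1, v2 = p1.diff(t), p2.diff(t)
    T = (m1 * (v1.T * v1)[0] + m2 * (v2.T * v2)[0]) / 2 \
        + (I1 * th1.diff(t) ** 2 + I2 * th2.diff(t) ** 2) / 2
    V = g * (m1 * p1[1] + m2 * p2[1])
    L = T - V
    tau1, tau2 = sp.symbols("tau1 tau2")
    # generalized forces for absolute angles: the inter-link torque tau2 acts
    # +tau2 on link 2 and -tau2 on link 1
    eqs = [sp.diff(sp.diff(L, th1.diff(t)), t) - sp.diff(L, th1) - (tau1 - tau2),
           sp.diff(sp.diff(L, th2.diff(t)), t) - sp.diff(L, th2) - tau2]
    sol = sp.solve(eqs, [th1.diff(t, 2), th2.diff(t, 2)], dict=True)[0]
    subs = {sp.Symbol(k, positive=True): v for k, v in PARAMS.items()}
    args = (th1, th2, th1.diff(t), th2.diff(t), tau1, tau2)
    return (sp.lambdify(args, sol[th1.diff(t, 2)].subs(subs), "numpy"),
            sp.lambdify(args, sol[th2.diff(t, 2)].subs(subs), "numpy"))


_F1, _F2 = _derive_forward_dynamics()


def simulate(dt, t_end=1.5, y0=(0.3, -0.2, 0.0, 0.0)):
    """Integrate the pendulum under the prescribed torques; returns (t, th1, th2)."""

    def rhs(t, y):
        a1, a2, w1, w2 = y
        return [w1, w2, _F1(a1, a2, w1, w2, tau1_fn(t), tau2_fn(t)),
                _F2(a1, a2, w1, w2, tau1_fn(t), tau2_fn(t))]

    ts = np.arange(0.0, t_end + dt / 2, dt)
    sol = solve_ivp(rhs, (0.0, t_end), list(y0), t_eval=ts, rtol=1e-11, atol=1e-12,
                    method="DOP853")
    return ts, sol.y[0], sol.y[1]


def inverse_torque_error(dt):
    """Max |recovered - prescribed| torque over both joints (interior nodes)."""
    ts, a1, a2 = simulate(dt)
    P = PARAMS
    seg1 = SegmentParams("foot_r", P["m1"], P["L1"], P["c1"], P["I1"])
    seg2 = SegmentParams("shank_r", P["m2"], P["L2"], P["c2"], P["I2"])
    u1 = np.stack([np.cos(a1), np.sin(a1)], -1)
    u2 = np.stack([np.cos(a2), np.sin(a2)], -1)
    joint2 = P["L1"] * u1
    z1 = P["c1"] * P["L1"] * u1
    z2 = joint2 + P["c2"] * P["L2"] * u2
    grav = (0.0, -P["g"])

    def dd(X):
        return central_second_difference(X, dt)[1:-1]

    F2, T2 = segment_solve(seg2, dd(z2), dd(a2), z2[1:-1], joint2[1:-1], gravity=grav)
    _, T1 = segment_solve(seg1, dd(z1), dd(a1), z1[1:-1],
                          np.zeros((len(ts) - 2, 2)),
                          applied_forces=((-F2, joint2[1:-1]),),
                          applied_torques=(-T2,), gravity=grav)
    ti = ts[1:-1]
    return max(np.max(np.abs(T1 - tau1_fn(ti))), np.max(np.abs(T2 - tau2_fn(ti))))
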