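# Methods

## Model

The walking model is a planar chain of seven rigid segments — right and left
foot, shank and thigh, plus one head–arms–trunk (HAT) segment — connected by
frictionless pin joints. The two hips are lumped into a single hip joint and
the two shoulders into a single shoulder point, so the chain branches at the
hip. Nine generalized coordinates describe the configuration: the seven
segment angles, measured counter-clockwise from the +x (walking) axis, and
the hip position `(x_hip, y_hip)`. Segment axes run proximal→distal with
"proximal" meaning closer to the hip (trunk: hip→shoulder; foot: ankle→MTP).
This is one internal convention used everywhere; any sign conventions used
for *reporting* (e.g. flexion-positive torques) belong to a presentation
layer and are deliberately not baked into the mechanics.

Segment parameters come from a standard anthropometric table (mass, COM and
radius-of-gyration fractions per segment), shipped as an editable YAML file
rather than hard-coded: these cadaver-derived fractions are configuration,
not ground truth. The HAT entry absorbs head and arms so the seven modelled
masses sum to the full subject mass — the model must be dynamically complete
for whole-body residuals to be meaningful. Segment lengths are estimated as
time-averaged inter-marker distances, with the lumped hip (mean of the two
trochanter markers) and shoulder (mean of the two acromions) formed per frame
before distancing. Markers are assumed to sit at the joint axes, so no
marker-to-segment calibration is needed.

## Differentiation

All accelerations use the three-point central-difference stencil
`(x[i−1] − 2x[i] + x[i+1])/dt²`, applied *directly to Cartesian COM
positions* evaluated per node — not by chain-ruling differentiated
generalized coordinates, a variant that trades a slightly lower marker
mismatch for high-frequency oscillation of the optimized coordinates.
Angular velocities use the matching first-order central stencil. Both are
exact on quadratics and second-order accurate otherwise. The two boundary
nodes, where the stencil does not fit, carry no dynamics: equations of
motion and constraints are evaluated on interior nodes only, while the
marker objective runs over all N nodes. The boundary coordinates remain free
decision variables that influence the interior accelerations.

## Inverse dynamics and residuals

Classical analysis proceeds bottom-up per leg: the foot's three planar
Newton–Euler equations are solved for the ankle force and torque (ground
reaction force and COP are inputs), the reaction is reversed onto the shank,
and so on to the hip. The trunk receives both hip reactions at the lumped
hip; the residual force closes its force balance and the residual torque
closes its torque balance *given* the residual force acting at a chosen
application point (shoulder by default, trunk COM as the alternative — the
choice shifts the residual torque by exactly the moment of the residual
force over the point shift, which is why the torque value alone is
meaningless). During swing the external force is exactly zero and the
undefined COP is excluded from all moment sums.

An independent cross-check, `whole_body_residual`, sums Newton's second law
over all segments without recursion; internal joint loads cancel pairwise,
so it must (and does, to rounding) agree with the recursion. The recursion
is additionally validated against a symbolically derived two-link pendulum:
torques prescribed, motion integrated, inverse dynamics recovers the torques
with the expected O(dt²) error.

## The constrained optimization

Decision variables are the 9N coordinate values at the nodes directly — no
spline or other reparameterization — matching the structure of the problem:
minimize the weighted squared marker mismatch subject to zero scaled residual
force and torque at every interior node (3(N−2) equality constraints), with
the external loads as fixed parameters. Constraints are scaled by body weight
(forces) and body weight × trunk length (torques) so all entries are
dimensionless and comparable; the tolerance applies to these scaled values
(default 1e-6, typically met at 1e-9 or better).

The default backend is an equality-constrained Gauss–Newton SQP written for
this structure:

- The objective is a small-residual least-squares; its Jacobian is analytic
  and block-diagonal over nodes (each marker depends only on its own node's
  nine coordinates through a short trigonometric chain), giving a sparse
  Gauss–Newton Hessian.
- Each constraint node touches only trajectory nodes i−1, i, i+1, so the
  constraint Jacobian is banded. It is obtained by complex-step
  differentiation with a 3-node coloring: 27 structured evaluations per
  iteration regardless of N, exact to machine precision. (A forward-difference
  fallback exists; the whole kinematics→dynamics path is written to be
  complex-safe.)
- Each iteration solves one sparse KKT system (9N + 3(N−2) unknowns) and
  applies a backtracking line search on an l1 merit function.

Convergence requires feasibility (max scaled violation below tolerance) plus
first-order stationarity or a negligible step. On a noise-free consistent
start the first KKT step is null and the initial guess is returned unchanged.
A generic `scipy.optimize` trust-constr backend (same objective gradient and
sparse constraint Jacobian) is retained as an option and agrees with the SQP
on test problems; it is roughly two orders of magnitude slower, which is why
the structured solver is the default. Typical cost for a 120-node stride:
5–10 iterations, well under a second on one CPU.

The initial guess inverts the markers directly (hip = mean of trochanters,
angles by `atan2` of distal−proximal estimated points, unwrapped over time),
which reproduces the generating coordinates exactly on noise-free data.
Multiple local minima are not handled beyond this deterministic start; from
measurement-quality starting points the solver has always converged in our
testing, and non-convergence is reported in the result rather than raised.

## Measurement conditioning

Kinematic series are filtered with a zero-lag (forward–backward) 4th-order
Butterworth low-pass at 10 Hz, force-plate channels at 20 Hz before the COP
is computed as `x = (Mz + h·Fx)/Fy` and the record is downsampled (sample
dropping after filtering, e.g. 200→100 Hz). Frames whose vertical force is
below a contact threshold are flagged swing with force zeroed and COP
undefined; the threshold defaults to 1% of body weight — a concrete stand-in
for "force very close to zero", configurable. Strides are bounded by
consecutive right-foot toe-offs (first below-threshold sample of a swing
run); a stride is kept only if both feet show a contiguous swing interval.
Windows include both bounding toe-off samples so that stride detection is
idempotent on an extracted stride.

## Synthetic trials

The generator provides what no measured dataset can: certified ground truth.
Kinematics are sums of low-order harmonics of the stride frequency (legs in
antiphase, trunk near-vertical, forward hip drift), with seeded jitter of
amplitudes and phases so that every seed is a distinct but comparable
stride. Loads are then *derived*: the total force demand
`ΣF = Σ m_k(a_k − g)` uses the same central-difference accelerations as the
inverse dynamics, the right foot carries a smooth share λ(t) (exactly 0 in
right swing, 1 in left swing), and the torque demand is split in the same
proportion, which places the active feet's centers of pressure at the common
zero-moment point on the walking surface. Consistency therefore holds on the
discrete grid by construction — the fixture certificate asserts residuals
below 1e-9 of body weight — rather than only in an O(dt²) sense, which makes
the construction-based test oracles exact. Marker noise is i.i.d. Gaussian
per coordinate (default σ = 5 mm) plus an optional slow sinusoidal artifact
emulating skin movement.

Defaults define the emulated study conditions: 120 nodes at 100 Hz (a 1.2 s
stride, comfortable walking speed), subject mass 66.1 kg, σ = 5 mm. What the
generator does *not* emulate: planted stance feet (the harmonic legs never
stop relative to the ground, so an overall COP realism check against the
stance ankle is available but off by default), physiological GRF shapes
(forces are whatever consistency demands), soft-tissue dynamics, and
systematic anthropometric error. Consequently the residuals produced by pure
i.i.d. noise are spectrally whiter, and after 10 Hz filtering somewhat
smaller in low-frequency content, than those of real skin-artifact-laden
data — passing tests demonstrate the algorithm's correctness and its
behaviour under known noise, not field performance on any particular lab's
data.

## Numerical choices and limitations

- Problem sizes in the shipped tests and the reproduction script — 120-node
  single strides, 10-stride studies, 50-seed recovery runs — were chosen as
  the smallest sizes at which the stride structure (two swing phases, double
  support) and the statistics of interest are well resolved.
- The merit penalty and Gauss–Newton regularization scale with the objective,
  so rescaling all marker weights by a constant leaves the iterates, and the
  optimum, unchanged.
- Degenerate inputs fail loudly and early: short series, non-uniform time
  grids, mismatched grids between markers/loads/guess, non-positive masses
  or lengths, out-of-range fractions, unknown configuration keys.
- The relative torque measure divides by the RMS of the classical torque
  series and is flagged undefined (NaN) when that reference is identically
  zero; it is intentionally asymmetric in its arguments.
- Out of scope by design: 3D mechanics, optimization of body-segment
  parameters, strict periodicity constraints, joint-contact force
  decomposition, spline/Kalman differentiation variants, and binary motion
  file formats (a minimal TRC text importer is included).
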