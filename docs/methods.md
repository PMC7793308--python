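# Methods

`collosim` solves optimal-control problems over small planar
musculoskeletal models by direct collocation. This note records the models
it implements, the numerical choices behind the solver, what the built-in
verification fixtures do and do not demonstrate, and the design decisions
taken where several reasonable options existed.

## Multibody models

A model is a tree of rigid bodies in the plane connected by pin, slider,
weld, or free-planar joints, optionally closed by explicit holonomic
constraints (point coincidence between two body-fixed points, or linear
coordinate coupling `q_a − c·q_b − d = 0`). The equations of motion are
derived symbolically from the Lagrangian of the declared tree (sympy) and
lambdified to vectorized numpy callables, so the mass matrix `M(q)`,
velocity bias `c(q,u)`, generalized gravity, muscle path lengths, moment
arms (`−∂l/∂q`), and constraint Jacobians are exact — the only numerical
differentiation anywhere in the stack is the solver-side finite
differencing of the transcribed constraint functions.

Forces come from:

* **muscles** — straight-line paths through body-fixed points, force from
  the Hill model below, mapped through the moment arms;
* **torsional springs** — `τ = −k (q − q₀)` on a named coordinate;
* **ideal coordinate actuators** — `τ = gain · control` (also used as
  bounded "reserves" in the inverse tool);
* **smooth contact** — sphere against the ground half-space, Hertz-type
  normal force `k_c d_s^{3/2}(1 + 1.5 c_d v_n)` on the smoothed depth
  `d_s = (d + √(d² + ε²))/2` with regularized Coulomb friction
  `−μ F_n tanh(v_t/v_s)`; the smoothing constants default to `ε = 10⁻⁴ m`
  and `v_s = 0.05 m/s`, chosen so the force is C¹ for all depths at
  gait-like speeds;
* **gravity** — default `(0, −9.80665) m/s²`.

Constrained forward dynamics solves the KKT system
`[M Gᵀ; G 0][q̈; −λ] = [τ − c; −(Ġu)]` (optional Baumgarte stabilization,
off by default). Inverse dynamics returns `M q̈ + c` net of gravity,
springs, and contact, i.e. the generalized force the actuators and muscles
must supply. Joint reaction loads are computed from the Newton force
balance of the subtree distal to the joint, minus external (muscle,
contact) forces applied to subtree bodies, and are reported as force
components in the child-body frame; the frame and component set are
configurable because no universal convention exists.

## Muscle model

Each musculotendon actuator is a damped Hill-type muscle with four smooth
characteristic curves (all normalized):

* active force–length `f_act = exp(−(l̃−1)²/0.45)`,
* passive force–length `f_pass = (e^{4(l̃−1)/0.6} − 1)/(e⁴ − 1)` (slightly
  negative below optimal length — a property of the curve family, kept
  as-is),
* force–velocity `f_v = d₁ ln(d₂ṽ + d₃ + √((d₂ṽ+d₃)²+1)) + d₄` with
  `(d₁..d₄) = (−0.318, −8.149, −0.374, 0.886)` (≈0 at maximal shortening,
  ≈1.002 isometric),
* tendon force–length `f_T = 0.2 e^{35(l̃_T − 0.995)} − 0.25`, clamped
  smoothly non-negative through a softplus of sharpness 100 when used as
  a force (the raw curve is ≈ −0.012 at slack length).

Activation follows the smooth first-order lag
`ȧ = [(f+½)/(τ_act(0.5+1.5a)) + (½−f)(0.5+1.5a)/τ_deact](e−a)` with
`f = ½ tanh(0.1(e−a))`, `τ_act = 15 ms`, `τ_deact = 60 ms`. Excitations
and activations live in `[0.01, 1]`; the strictly positive floor keeps the
compliant-tendon equilibrium well-posed.

With a **rigid tendon**, fiber kinematics follow from the path length
under constant-thickness pennation. With a **compliant tendon**, the
normalized tendon force is a state; its scaled derivative (factor
50 s⁻¹, control in `[−1, 1]`) is an extra control, and the fiber–tendon
equilibrium residual (with fiber damping β = 0.1) is enforced as an
equality path constraint at every collocation point. Damping makes that
residual strictly monotone in the tendon force, so the equilibrium is
unique; it can also produce small compressive fiber forces at low
activation and fast shortening, which is documented rather than
suppressed.

## Transcription

The continuous problem (states `x = [q, u, a, f̃_T]`, controls
`[excitations, actuator controls, tendon-rate controls]`) is discretized
on a uniform normalized mesh, trapezoidal (`N+1` points, second order) or
Hermite–Simpson (`2N+1` points including interval midpoints, third
order). Free final time is handled by a single duration variable with
`h = Δt/N`; the start time is always fixed. The decision vector is
`[Δt? | states | per-point controls (incl. λ and implicit-mode
accelerations) | midpoint velocity corrections γ | parameters]`.

* **Kinematic constraints** use multipliers-as-controls: `φ(q) = 0` and
  `G(q)u = 0` at every mesh point, `Gᵀλ` applied in the dynamics
  everywhere, and at Hermite–Simpson midpoints the position derivative is
  augmented with `Gᵀγ`, `|γ| ≤ 0.1`. Midpoint multiplier values are tied
  to the mesh-point average (λ piecewise-linear over the full interval):
  with free midpoints the multipliers can oscillate point-to-point while
  every defect remains satisfied, leaving pointwise accelerations
  non-physical; the tie removes the oscillation without affecting the
  represented solution family. Physical controls and γ remain free at
  midpoints.
* **Implicit dynamics** add the generalized accelerations `w` as
  per-point controls (bounded, default ±1000), replace `u̇` by `w` in the
  defects, and enforce `M(q)w + c(q,u) − τ = 0` at every collocation
  point.
* **Free parameters** (spring stiffness, body mass symbolically; muscle
  maximum isometric force and actuator gain as runtime scales) appear as
  one trailing NLP variable each and flow into every dynamics evaluation.

Goal integrals use the quadrature consistent with the scheme (trapezoid
or Simpson weights); effort goals are not normalized by duration, and
tracking references are cubic-interpolated with extrapolation forbidden.
Objective gradients and (diagonal-plus-duration-coupling) Hessians are
analytic for the quadratic goals; the joint-reaction goal differentiates
its integrand by per-channel central differences and contributes no
Hessian (which only slows local convergence).

## Solving the nonlinear program

The NLP is solved with scipy's `trust-constr` interior-point method.
Constraint Jacobians are central finite differences (relative step 10⁻⁶)
compressed through the transcription's banded sparsity pattern, so one
Jacobian costs a few dozen constraint evaluations regardless of mesh
size. Defaults follow common practice for this problem class:
convergence tolerance 10⁻³ (KKT), constraint tolerance 10⁻³; the
verification fixtures tighten both.

Three solver-hardening measures matter in practice and are part of the
package's design:

1. **Termination.** Interior-point optimality measures can stall when
   many variables ride bounds (muscle problems spend most of the horizon
   on the excitation floor). Besides the solver's own gtol test, a
   callback declares convergence when the iterate is feasible, the
   barrier parameter has reached its target, and either the
   multiplier-scaled KKT norm (IPOPT-style scaling,
   `s_d = max(100, ‖v‖₁/m)/100`) is below tolerance with a stable
   objective, or the objective has stagnated over a 30-iteration window.
2. **Warm starts.** The solution of one problem seeds the next
   (mesh-continuation ladders, explicit→implicit switches, re-solves).
   Because the interior-point stage re-initializes its slack variables
   away from the supplied point, warm starts use a small initial barrier
   (10⁻⁶), and guesses that are already feasible on moderate-size
   programs (≤ 800 variables, all-equality constraints) first get an
   active-set SQP attempt (SLSQP), which typically finishes in a handful
   of iterations. Implicit-mode accelerations are seeded from forward
   dynamics at the guess so the dynamics residual starts at zero;
   midpoint velocity corrections ride along with solutions.
3. **Polish.** An optional SLSQP polish stage (`polish=True`) sharpens a
   stalled interior-point iterate; it is used where bound-riding optima
   need to be resolved tightly (e.g. the explicit/implicit equivalence
   checks).

The default initial guess is the midpoint of the variable bounds (zero
where unbounded), with initial/final state conditions expressed as
endpoint variable bounds so the guess honors them. Cold-started
predictive problems are solved through a mesh-continuation ladder —
coarse first, each solution seeding the next — which is the standard and,
in our experience, necessary practice for minimum-time and muscle-driven
problems.

## Verification fixtures and what they show

* **Linear tangent steering** (constant thrust acceleration 100 m/s²,
  reach altitude 5 m, horizontal speed 45 m/s, zero vertical speed in
  minimum time — the standard instance of this benchmark family). The
  oracle solves the two boundary equations of the closed form with a
  scalar root-find and evaluates all states analytically; it shares no
  code with the transcription. At 100 mesh intervals the collocation
  solution matches the oracle to RMS ≈ 10⁻⁶ over all states and the
  control on the mesh (bound 2.7×10⁻⁵). The fixture's convergence
  tolerance is gtol 10⁻⁹: trust-constr's gtol is an *unscaled*
  Lagrangian-gradient norm, and on a problem with states of magnitude ~45
  this corresponds to the multiplier-scaled 10⁻⁶ that interior-point
  solvers conventionally report. The RMS is computed over states plus
  control at every trajectory point; which variables enter such an RMS is
  a convention, and this one is the most demanding natural choice.
* **Suspended point mass** (1 kg, muscles anchored at x = −0.16, 0,
  +0.16 m on the ceiling; rest-to-rest transport from (−0.08, −0.18) to
  (+0.08, −0.18) m; squared-excitation weight 1, final-time weight 0.1;
  Hermite–Simpson, N = 50). Muscle parameters: F_iso = 40 N, optimal
  fiber length 0.20 m, tendon slack 0.05 m, rigid tendons, no pennation.
  The fiber length is sized so the normalized operating range over the
  motion stays in ≈[0.65, 1.25]: with substantially shorter fibers the
  exponential passive curve produces forces orders of magnitude above
  F_iso at reachable poses and the fixture stops being a muscle-driven
  problem at all.
  - *Time-stepping consistency*: re-integrating the predicted controls
    with an adaptive Runge–Kutta scheme (rtol 10⁻⁸, piecewise-linear
    control interpolation — the same rule the transcription assumes)
    reproduces the predicted positions to ≈0.01% of the travel distance
    (bound 1.8%).
  - *Tracking recovery*: tracking the predicted states (weight 10,
    squared-excitation weight 0.001, horizon fixed to the predicted
    duration) returns the predicted activations to ≈0.06% of their peak
    (bound 0.47%).
* **Sliding-mass minimum time** converges to the bang-bang closed form;
  trapezoidal errors decay cleanly as O(h²) (used for the monotone
  normalized-objective convergence check), while Hermite–Simpson reaches
  the 10⁻⁴ s accuracy bound at N = 40 (its errors then sit at the solver
  tolerance floor, so strict monotonicity is asserted only up to that
  floor).
* **Mode equivalence**: sliding mass, the coupler-constrained double
  pendulum, and the suspended mass solved with explicit and implicit
  dynamics agree in objective to ≈10⁻⁵ relative.
* **Sit-to-stand with an assistive spring**: a 35 kg torso pendulum
  (com 0.4 m above the knee pin) with an extensor and a flexor muscle,
  knee from 1 rad (squat) to 0 (stand), rest to rest, squared excitations
  (weight 1) plus duration (weight 1). Each actuator stands in for a
  muscle group, so its excitation carries channel weight 5 — without it a
  1-DOF model degenerates into a pure minimum-time problem. The motion
  starts from a steady muscle state (activation = excitation at t₀), so
  the optimizer cannot conjure a free pre-activated burst. Freeing the
  spring stiffness (bounds [0, 300] N·m/rad, seeded at 0 from the
  unassisted solution) lowers the objective and cuts the extensor's mean
  activation by ≈25%. The extensor's *pointwise* activation maximum still
  touches 1.0 for one or two collocation points in both cases — a
  structural feature of effort-plus-duration objectives on one degree of
  freedom — so the "activity decreases" audit uses the mean.
* **Stiffness recovery**: tracking a passive spring-pendulum swing
  synthesized by time-stepping with k = 50 N·m/rad recovers the stiffness
  to ≈0.03%.
* **Inverse-tool recovery**: inverting a forward-simulated suspended-mass
  motion returns the known activations to ≈1% of peak with reserve forces
  ≈0.02 N (reserves default to ±2.5 per coordinate, the usual published
  guideline bound). Kinematics are differentiated through a cubic Hermite
  interpolant (positions and speeds pinned to the data, analytic second
  derivative, no filtering); a smoothing option is not provided because
  the package's inputs are synthetic and noise-free.

What the fixtures do **not** show: behavior on 3-D models, wrapping
muscle paths, measured (noisy, soft-tissue-artifact) kinematics, contact-
rich motions, or models with hundreds of variables per time point. The
fixtures verify the mathematics of the transcription and the dynamics at
desk scale; conclusions about real experimental data require validation
against that data.

## Known limitations

* Planar mechanics only; minimal-coordinate trees plus explicit holonomic
  constraints; straight-line muscle paths (via points, no wrapping).
* Uniform meshes; no mesh refinement; single phase; no unilateral
  (complementarity) constraints.
* The interior-point backend needs mesh continuation on cold-started
  minimum-time and muscle-driven problems, and the implicit dynamics mode
  is practical mainly with a warm start from an explicit solution.
* Effort goals cannot be duration-normalized; tracking costs are not
  normalized by reference range or channel count (both documented
  choices).
* Muscle-curve constants other than the maximum isometric force are not
  registrable as free optimization parameters.
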