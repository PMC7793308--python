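# collosim

Direct-collocation optimal control for small muscle-driven planar
multibody models.

Musculoskeletal questions — *which muscle activity produced an observed
motion? what motion would a model choose? how stiff should an assistive
spring be?* — are naturally optimal-control problems: find time-varying
controls (muscle excitations, torques) and parameters that minimize a
cost subject to the body's differential-algebraic dynamics. `collosim`
implements the direct-collocation approach to these problems at desk
scale, for researchers and students who want a fully inspectable stack:
planar rigid-body models with exact symbolically derived dynamics,
smooth Hill-type muscles, holonomic kinematic constraints, and a sparse
nonlinear-program transcription with verification experiments built in
as first-class fixtures.

## The method

A problem is posed over a model's continuous state
`x = (q, u, a, f̃_T)` — generalized coordinates and speeds, muscle
activations, and normalized tendon forces for compliant-tendon muscles —
and controls `c` (excitations, actuator inputs):

```
minimize    Σ_k w_k ∫ g_k(x, c, t) dt  +  Σ_k w_k h_k(x(t_f), t_f)
subject to  q̇ = u,   M(q) u̇ = τ(q, u, a, c) + G(q)ᵀλ − c(q, u)
            ȧ = f_act(e, a),   tendon equilibrium (compliant muscles)
            φ(q) = 0,  G(q) u = 0          (kinematic constraints)
            bounds, boundary and path constraints
```

Direct collocation turns this into a finite nonlinear program: states and
controls become variables on a mesh of time points, and the dynamics are
enforced as algebraic *defect* constraints — trapezoidal
(`x_{k+1} − x_k − h/2 (f_k + f_{k+1})`, second order) or Hermite–Simpson
(Hermite interpolation + Simpson integration defects, third order, with a
collocation point at each interval midpoint, so `N` mesh intervals give
`2N+1` time points). Multibody dynamics can be enforced explicitly
(forward dynamics) or implicitly (accelerations as variables, the
inverse-dynamics residual as a path constraint). Kinematic constraints
enter through Lagrange multipliers as per-point variables with bounded
velocity-correction variables at Hermite–Simpson midpoints. The program
is solved with an interior-point method using sparsity-compressed
finite-difference constraint Jacobians and analytic objective
derivatives. `docs/methods.md` has the full account.

Three standard workflows are packaged as tools:

* **predict** — solve for motion and controls from goals alone
  (`solve_problem`, usually through a mesh-continuation ladder);
* **track** — solve for motion and controls that stay close to reference
  data while minimizing effort (`solve_track`);
* **inverse** — prescribe the kinematics exactly and solve the muscle
  redundancy problem for excitations and bounded reserves
  (`solve_inverse`).

## A worked example

`examples/sliding_mass_minimum_time.py` solves the classic minimum-time
benchmark — a 1 kg mass must slide 1 m, rest to rest, with the force
bounded by ±10 N:

```
status:            converged
minimum time:      0.632456 s
analytic optimum:  0.632456 s
difference:        6.24e-09 s
The force profile is +10 N for the first half and -10 N for the second half;
force at 1/4 and 3/4 time: +10.00, -10.00 N
```

The printed minimum time matches the bang-bang closed form
`2·sqrt(m·d/F_max)` to nanoseconds, and the solved control saturates at
the expected bounds on both sides of the switch.

`examples/optimize_spring_stiffness.py` runs the assistive-device
experiment — a sit-to-stand pendulum with an extensor and a flexor
muscle, re-solved with the stiffness of a knee spring as a free
optimization variable:

```
unassisted objective: 0.7103 (duration 0.570 s)
assisted objective:   0.6931 (duration 0.576 s)
optimal stiffness:    53.3 N m/rad
mean extensor activation: 0.141 -> 0.107
```

Freeing the stiffness can only lower the cost (zero stiffness stays
feasible), and the optimized spring takes about a quarter of the
extensor's work.

The other scripts in `examples/` cover motion prediction with a
time-stepping cross-check, tracking recovery of known muscle activity,
the muscle-redundancy inverse tool, and the analytic steering benchmark.
A thin CLI mirrors the library (`collosim solve examples/sliding_mass.yaml`,
`collosim inverse`, `collosim track`, `collosim forward-check`,
`collosim converge`, `collosim verify`).

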