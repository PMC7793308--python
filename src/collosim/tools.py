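"""Standard-problem tools: muscle redundancy (inverse), motion tracking,
and mesh-continuation solving.

These wrap :func:`collosim.problem.solve_problem` with the setups a
practitioner reaches for first:

* :func:`solve_inverse` — kinematics are prescribed exactly (twice
  differentiated cubic interpolants); solve only for muscle controls/states
  and bounded reserve actuators under a squared-controls objective.
* :func:`solve_track` — solve for both a motion and its controls, weighing
  deviation from reference data against control effort.
* :func:`solve_with_continuation` — chain solutions over an increasing mesh
  ladder (the solution of each solve seeds the next), which is how
  cold-started predictive problems are made reliable.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline

from .model import ModelSpec
from .problem import (ControlEffortGoal, ProblemDef, StateTrackingGoal,
                      solve_problem)
from .system import MuscularSystem, PrescribedMotionSystem
from .trajectory import Solution, Trajectory
from .transcription import TranscriptionConfig

__all__ = ["solve_inverse", "solve_track", "solve_with_continuation"]


def solve_with_continuation(problem: ProblemDef, config: TranscriptionConfig,
                            mesh_schedule=(), guess=None, verbose: int = 0):
    """Solve through a ladder of mesh densities, ending at ``config``.

    ``mesh_schedule`` lists coarser mesh-interval counts solved first; each
    solution becomes the next guess.  Returns (Solution, NLPStructure) of
    the final solve.
    """
    import dataclasses
    for N in mesh_schedule:
        coarse = dataclasses.replace(config, num_mesh_intervals=N)
        guess, _ = solve_problem(problem, coarse, guess=guess,
                                 verbose=verbose)
    return solve_problem(problem, config, guess=guess, verbose=verbose)


def _kinematic_splines(model: ModelSpec, kinematics: Trajectory):
    """Cubic interpolants of the coordinate columns with analytic first and
    second derivatives.  When matching speed columns (``<coord>_u``) are
    present the interpolant is the cubic Hermite through positions and
    speeds, which pins the first derivative to the data and keeps the
    second derivative accurate at the span ends."""
    from scipy.interpolate import CubicHermiteSpline

    coords = model.coordinate_names()
    missing = [c for c in coords if c not in kinematics.columns]
    if missing:
        raise KeyError(f"kinematics missing coordinate column(s) {missing}")
    Q = np.stack([kinematics[c] for c in coords], axis=1)
    have_speeds = all(f"{c}_u" in kinematics.columns for c in coords)
    if have_speeds:
        U = np.stack([kinematics[f"{c}_u"] for c in coords], axis=1)
        qs = CubicHermiteSpline(kinematics.time, Q, U)
    else:
        qs = CubicSpline(kinematics.time, Q)
    us = qs.derivative()
    qdds = us.derivative()
    return (lambda t: np.atleast_2d(qs(t)).reshape(np.size(t),
                                                   len(coords)).T,
            lambda t: np.atleast_2d(us(t)).reshape(np.size(t),
                                                   len(coords)).T,
            lambda t: np.atleast_2d(qdds(t)).reshape(np.size(t),
                                                     len(coords)).T)


def solve_inverse(model: ModelSpec, kinematics: Trajectory,
                  num_mesh_intervals: int = 25,
                  scheme: str = "hermite-simpson",
                  reserve_bound: float = 2.5,
                  excitation_effort_weight: float = 1.0,
                  reserve_effort_weight: float = 1.0,
                  convergence_tol: float = 1e-5,
                  constraint_tol: float = 1e-5,
                  t0: float = None, tf: float = None,
                  max_iterations: int = 3000,
                  mesh_schedule=(), extra_goals=()):
    """Muscle/actuator redundancy with exactly prescribed kinematics.

    The provided coordinate trajectories are interpolated with cubic
    splines; generalized speeds and accelerations are the analytic first
    and second derivatives of the interpolant (no filtering).  The force
    balance ``muscle + reserve generalized forces = inverse dynamics`` is an
    equality path constraint at every collocation point; the objective is
    the weighted squared controls.  Reserve actuators (one per coordinate,
    unit gain) are bounded by ``reserve_bound`` so muscles, not reserves,
    explain the motion.
    """
    span = (float(kinematics.time[0]), float(kinematics.time[-1]))
    t0 = span[0] if t0 is None else float(t0)
    tf = span[1] if tf is None else float(tf)
    if t0 < span[0] - 1e-12 or tf > span[1] + 1e-12 or tf <= t0:
        raise ValueError(f"horizon [{t0}, {tf}] outside the kinematics span "
                         f"[{span[0]}, {span[1]}]")
    qf, uf, qddf = _kinematic_splines(model, kinematics)
    sys_ = PrescribedMotionSystem(model, qf, uf, qddf,
                                  reserve_bound=reserve_bound)
    weights = {}
    for m in model.muscles:
        weights[f"{m.name}_excitation"] = excitation_effort_weight
    for c in model.coordinate_names():
        weights[f"reserve_{c}"] = reserve_effort_weight
    prob = ProblemDef(system=sys_, duration=tf - t0, t0=t0,
                      goals=[ControlEffortGoal(1.0,
                                               channel_weights=weights)]
                      + list(extra_goals))
    cfg = TranscriptionConfig(scheme=scheme,
                              num_mesh_intervals=num_mesh_intervals,
                              convergence_tol=convergence_tol,
                              constraint_tol=constraint_tol,
                              max_iterations=max_iterations)
    sol, _ = solve_with_continuation(prob, cfg, mesh_schedule)
    return sol


def solve_track(model: ModelSpec, reference: Trajectory,
                tracking_weight: float = 1.0,
                effort_weight: float = 0.001,
                channel_weights: dict = None,
                num_mesh_intervals: int = 25,
                scheme: str = "hermite-simpson",
                convergence_tol: float = 1e-5,
                constraint_tol: float = 1e-5,
                state_bounds: dict = None,
                fix_initial_state: bool = False,
                max_iterations: int = 3000,
                guess=None, extra_goals=()):
    """Track a reference motion with a muscle-driven model.

    Solves for both the motion and the controls: the cost weighs squared
    deviation of every state that appears in the reference (kinematics, and
    activations if present) against squared controls.  The horizon is fixed
    to the reference span.  The kinematic columns of the reference seed the
    initial guess; muscle-related variables start at the midpoint of their
    bounds, so recovered muscle activity is a result of the optimization,
    not of the seed.
    """
    sys_ = MuscularSystem(model)
    span = (float(reference.time[0]), float(reference.time[-1]))
    state_initial = {}
    if fix_initial_state:
        for nm in sys_.state_names:
            if nm in reference.columns:
                state_initial[nm] = float(reference[nm][0])
    prob = ProblemDef(system=sys_, duration=span[1] - span[0], t0=span[0],
                      state_bounds=dict(state_bounds or {}),
                      state_initial=state_initial,
                      goals=[StateTrackingGoal(reference,
                                               weight=tracking_weight,
                                               channel_weights=channel_weights),
                             ControlEffortGoal(effort_weight)]
                      + list(extra_goals))
    cfg = TranscriptionConfig(scheme=scheme,
                              num_mesh_intervals=num_mesh_intervals,
                              convergence_tol=convergence_tol,
                              constraint_tol=constraint_tol,
                              max_iterations=max_iterations)
    if guess is None:
        kin_cols = [c for c in model.coordinate_names()
                    if c in reference.columns]
        kin_cols += [f"{c}_u" for c in model.coordinate_names()
                     if f"{c}_u" in reference.columns]
        guess = Trajectory(reference.time,
                           {c: reference[c] for c in kin_cols},
                           name="kinematic_guess")
    sol, _ = solve_problem(prob, cfg, guess=guess)
    return sol
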