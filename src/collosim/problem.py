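"""User-facing optimal-control problem definition.

A :class:`ProblemDef` owns a continuous system, the time horizon, variable
bounds, a list of goals (cost terms), boundary constraints relating initial
and final states, path constraints, and free model parameters.  It is the
analog of a study definition: declarative, serializable, and decoupled from
the transcription that solves it.

Goals supply their own integrands *and* analytic gradients so the solver
never needs to finite-difference the objective; the quadrature rule applied
to integral goals is always the one consistent with the transcription
scheme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import model as md
from .system import MuscularSystem, _resolve_parameter
from .transcription import TranscriptionConfig, assemble_nlp, solve_nlp

__all__ = [
    "GoalSpec", "ControlEffortGoal", "StateTrackingGoal", "FinalTimeGoal",
    "JointReactionGoal", "PeriodicPair", "AverageSpeed",
    "InitialSteadyActivation", "ControlEnvelope", "Parameter", "ProblemDef",
    "register_parameter", "solve_problem",
]


# -- goals --------------------------------------------------------------------

class GoalSpec:
    """Base cost term.  ``is_integral`` goals return
    ``(g, dg/dx, dg/dc, dg/dt or None, dg/dp or None)`` from
    :meth:`integrand`; terminal goals return ``(value, d/dxT, d/ddt, d/dp)``
    from :meth:`terminal`."""

    is_integral = True
    label = "goal"
    weight = 1.0

    def bind(self, system):
        """Resolve names against a system before transcription."""

    def integrand(self, x, c, t, p):
        raise NotImplementedError

    def terminal(self, xT, dt, p):
        raise NotImplementedError

    def hessian(self, x, c, t, p):
        """Diagonal curvature of the integrand
        ``(gxx, gcc, gxt, gct, gtt)`` or None (treated as zero)."""
        return None


class ControlEffortGoal(GoalSpec):
    """Integral of the weighted sum of |control|^p (default squared
    controls).  Not normalized by duration unless requested."""

    label = "control_effort"

    def __init__(self, weight=1.0, exponent=2, channel_weights=None,
                 divide_by_duration=False):
        if exponent < 1:
            raise ValueError("effort exponent must be >= 1")
        if weight < 0:
            raise ValueError("goal weight must be >= 0")
        self.weight = float(weight)
        self.exponent = exponent
        self.channel_weights = channel_weights  # dict name -> w, or None
        self.divide_by_duration = divide_by_duration
        self._w = None

    def bind(self, system):
        names = system.control_names
        w = np.ones(len(names))
        if self.channel_weights is not None:
            w = np.zeros(len(names))
            for nm, val in self.channel_weights.items():
                if nm not in names:
                    raise KeyError(f"effort goal: unknown control {nm!r}")
                w[names.index(nm)] = val
        self._w = w * self.weight

    def integrand(self, x, c, t, p):
        pexp = self.exponent
        absc = np.abs(c)
        g = self._w @ absc ** pexp
        dgc = self._w[:, None] * pexp * absc ** (pexp - 1) * np.sign(c)
        if self.divide_by_duration:
            # handled by the caller through dt; implemented as g / dt would
            # break the quadrature split, so scale here using t span instead
            raise NotImplementedError(
                "duration-normalized effort is not supported")
        return g, np.zeros_like(x), dgc, None, None

    def hessian(self, x, c, t, p):
        pexp = self.exponent
        gcc = self._w[:, None] * pexp * (pexp - 1) \
            * np.abs(c) ** (pexp - 2) if pexp != 1 \
            else np.zeros_like(np.atleast_2d(c))
        z = np.zeros_like(np.atleast_2d(x))
        zc = np.zeros_like(np.atleast_2d(c))
        return z, gcc, z, zc, np.zeros(np.atleast_2d(x).shape[1])


class StateTrackingGoal(GoalSpec):
    """Integral of weighted squared deviation from a reference trajectory.

    The reference is interpolated with a cubic spline through the provided
    samples; evaluation outside the reference span is an error.
    """

    label = "state_tracking"

    def __init__(self, reference, weight=1.0, channel_weights=None):
        if weight < 0:
            raise ValueError("goal weight must be >= 0")
        self.weight = float(weight)
        self.reference = reference
        self.channel_weights = channel_weights
        self._cols = None

    def bind(self, system):
        from scipy.interpolate import CubicSpline
        names = system.state_names
        ref = self.reference
        cols = [nm for nm in names if nm in ref.columns]
        if self.channel_weights is not None:
            for nm in self.channel_weights:
                if nm not in names:
                    raise KeyError(f"tracking goal: unknown state {nm!r}")
            cols = [nm for nm in cols
                    if self.channel_weights.get(nm, 0.0) != 0.0]
        if not cols:
            raise ValueError("tracking goal: reference shares no columns "
                             "with the system states")
        self._idx = np.array([names.index(nm) for nm in cols])
        w = np.array([1.0 if self.channel_weights is None
                      else self.channel_weights.get(nm, 0.0) for nm in cols])
        self._w = w * self.weight
        self._span = (float(ref.time[0]), float(ref.time[-1]))
        self._spline = CubicSpline(ref.time,
                                   np.stack([ref[nm] for nm in cols], axis=1))
        self._dspline = self._spline.derivative()
        self._ddspline = self._dspline.derivative()

    def _ref(self, t):
        t = np.asarray(t)
        lo, hi = self._span
        if t.min() < lo - 1e-9 or t.max() > hi + 1e-9:
            raise ValueError(
                f"tracking reference spans [{lo}, {hi}] but was evaluated "
                f"at [{t.min()}, {t.max()}] (extrapolation forbidden)")
        return self._spline(np.clip(t, lo, hi)).T, \
            self._dspline(np.clip(t, lo, hi)).T

    def integrand(self, x, c, t, p):
        ref, dref = self._ref(t)
        err = x[self._idx] - ref
        g = self._w @ err ** 2
        dgx = np.zeros_like(x)
        dgx[self._idx] = 2.0 * self._w[:, None] * err
        dgt = -2.0 * self._w @ (err * dref)
        return g, dgx, np.zeros_like(c), dgt, None

    def hessian(self, x, c, t, p):
        ref, dref = self._ref(t)
        lo, hi = self._span
        ddref = self._ddspline(np.clip(np.asarray(t), lo, hi)).T
        err = x[self._idx] - ref
        gxx = np.zeros_like(np.atleast_2d(x))
        gxx[self._idx] = 2.0 * self._w[:, None]
        gxt = np.zeros_like(np.atleast_2d(x))
        gxt[self._idx] = -2.0 * self._w[:, None] * dref
        gtt = 2.0 * self._w @ (dref ** 2 - err * ddref)
        zc = np.zeros_like(np.atleast_2d(c))
        return gxx, zc, gxt, zc, gtt


class FinalTimeGoal(GoalSpec):
    """weight * t_f  (t_f = t0 + duration)."""

    label = "final_time"
    is_integral = False

    def __init__(self, weight=1.0):
        if weight < 0:
            raise ValueError("goal weight must be >= 0")
        self.weight = float(weight)
        self.t0 = 0.0

    def bind(self, system):
        pass

    def terminal(self, xT, dt, p):
        return (self.weight * (self.t0 + dt), np.zeros_like(xT),
                self.weight, None)


class JointReactionGoal(GoalSpec):
    """Integral of the squared norm of the reaction force at a joint
    (force components only by default; configurable).  Gradients by
    per-channel central differences of the integrand."""

    label = "joint_reaction"

    def __init__(self, model, joint_child, weight=1.0, components=(0, 1)):
        self.weight = float(weight)
        self.model = model
        self.joint_child = joint_child
        self.components = tuple(components)
        self._sys = None

    def bind(self, system):
        self._sys = system
        md._engine_for(self.model)  # fail early on unknown joint
        if self.joint_child not in {j.child for j in self.model.joints}:
            raise KeyError(f"unknown joint (child {self.joint_child!r})")

    def _load_sq(self, x, c, p):
        sys = self._sys
        q, u, a, ft = sys.split_state(x)
        T = q.shape[1]
        st = md.ContinuousState(q, u, a if sys.nmus else np.zeros((0, T)), ft)
        ctrl = np.atleast_2d(c)[:sys.nmus + sys.nact]
        F = md.joint_reaction_load(self.model, st, ctrl,
                                   joint_child=self.joint_child)
        F = np.atleast_2d(F)[list(self.components)]
        return self.weight * np.sum(F * F, axis=0)

    def integrand(self, x, c, t, p):
        g = self._load_sq(x, c, p)
        dgx = np.zeros_like(np.atleast_2d(x))
        dgc = np.zeros_like(np.atleast_2d(c))
        eps = 1e-6
        for i in range(dgx.shape[0]):
            xp = x.copy(); xp[i] += eps
            xm = x.copy(); xm[i] -= eps
            dgx[i] = (self._load_sq(xp, c, p)
                      - self._load_sq(xm, c, p)) / (2 * eps)
        for j in range(self._sys.nmus + self._sys.nact):
            cp = c.copy(); cp[j] += eps
            cm = c.copy(); cm[j] -= eps
            dgc[j] = (self._load_sq(x, cp, p)
                      - self._load_sq(x, cm, p)) / (2 * eps)
        return g, dgx, dgc, None, None


# -- boundary constraints -----------------------------------------------------

class _BoundarySpec:
    n_rows = 1

    def bind(self, system):
        pass

    def residual(self, x0, xT, c0, cT, dt, p):
        raise NotImplementedError


class PeriodicPair(_BoundarySpec):
    """x_final(final_state) - sign * x_initial(initial_state) = 0; sign=-1
    expresses mediolateral-style symmetry pairings."""

    def __init__(self, final_state, initial_state=None, sign=1.0):
        self.final_state = final_state
        self.initial_state = initial_state or final_state
        self.sign = float(sign)

    def bind(self, system):
        for nm in (self.final_state, self.initial_state):
            if nm not in system.state_names:
                raise KeyError(f"periodic pairing references unknown state "
                               f"{nm!r}")
        self._i = system.state_names.index(self.final_state)
        self._j = system.state_names.index(self.initial_state)

    def residual(self, x0, xT, c0, cT, dt, p):
        return xT[self._i] - self.sign * x0[self._j]


class AverageSpeed(_BoundarySpec):
    """(q(tf) - q(t0)) / duration - v_target = 0 for one coordinate."""

    def __init__(self, coordinate, target):
        self.coordinate = coordinate
        self.target = float(target)

    def bind(self, system):
        if self.coordinate not in system.state_names:
            raise KeyError(f"average-speed constraint on unknown coordinate "
                           f"{self.coordinate!r}")
        self._i = system.state_names.index(self.coordinate)

    def residual(self, x0, xT, c0, cT, dt, p):
        return (xT[self._i] - x0[self._i]) / dt - self.target


class InitialSteadyActivation(_BoundarySpec):
    """Start from a steady muscle state: activation equals excitation at
    the initial time (the activation dynamics' fixed point), so the
    optimizer cannot conjure a free pre-activated burst."""

    def __init__(self, muscle):
        self.muscle = muscle

    def bind(self, system):
        sname = f"{self.muscle}_activation"
        cname = f"{self.muscle}_excitation"
        if sname not in system.state_names \
                or cname not in system.control_names:
            raise KeyError(f"no muscle {self.muscle!r} in the system")
        self._i = system.state_names.index(sname)
        self._j = system.control_names.index(cname)

    def residual(self, x0, xT, c0, cT, dt, p):
        return x0[self._i] - c0[self._j]


# -- path constraints ---------------------------------------------------------

class ControlEnvelope:
    """Time-varying box ``lower(t) <= control <= upper(t)`` enforced at every
    collocation point (e.g. an EMG-derived excitation envelope)."""

    n_rows = 1

    def __init__(self, control, lower, upper):
        self.control = control
        self._lower, self._upper = lower, upper
        self.time_varying = callable(lower) or callable(upper)

    def bind(self, system):
        if self.control not in system.control_names:
            raise KeyError(f"control envelope on unknown control "
                           f"{self.control!r}")
        self._j = system.control_names.index(self.control)

    def lower(self, t):
        return self._lower(t) if callable(self._lower) \
            else np.full(np.size(t), self._lower)

    def upper(self, t):
        return self._upper(t) if callable(self._upper) \
            else np.full(np.size(t), self._upper)

    def residual(self, x, c, t, p):
        return c[self._j]

    def sparsity_cols(self, nlp, tp):
        return np.array([nlp.off_c + tp * nlp.nc + self._j])


@dataclass
class Parameter:
    """A scalar model property optimized alongside the trajectory."""
    path: str
    bounds: tuple


# -- problem ------------------------------------------------------------------

@dataclass
class ProblemDef:
    """Continuous optimal-control problem over one system.

    ``duration`` may be a float (fixed) or an interval (free final time;
    t0 is always fixed).  Bounds dictionaries override the system defaults
    per state/control name.  ``state_initial`` / ``state_final`` entries
    become boundary equality constraints.
    """

    system: object
    duration: object = 1.0
    t0: float = 0.0
    state_bounds: dict = field(default_factory=dict)
    control_bounds: dict = field(default_factory=dict)
    state_initial: dict = field(default_factory=dict)
    state_final: dict = field(default_factory=dict)
    goals: list = field(default_factory=list)
    boundary_constraints: list = field(default_factory=list)
    path_constraints: list = field(default_factory=list)
    parameters: list = field(default_factory=list)

    # ---- resolution helpers used by the transcription

    @property
    def duration_bounds(self):
        if np.isscalar(self.duration):
            return float(self.duration), float(self.duration)
        lo, hi = self.duration
        return float(lo), float(hi)

    def _resolve(self, names, defaults, overrides, kind):
        for nm in overrides:
            if nm not in names:
                raise KeyError(f"bounds given for unknown {kind} {nm!r}")
        out = np.empty((len(names), 2))
        for i, nm in enumerate(names):
            lo, hi = overrides.get(nm, defaults.get(nm, (-math.inf,
                                                         math.inf)))
            out[i] = (lo, hi)
        return out

    def resolved_state_bounds(self):
        return self._resolve(self.system.state_names,
                             self.system.default_state_bounds(),
                             self.state_bounds, "state")

    def resolved_control_bounds(self):
        return self._resolve(self.system.control_names,
                             self.system.default_control_bounds(),
                             self.control_bounds, "control")

    @property
    def boundary_specs(self):
        return list(self.boundary_constraints)

    def endpoint_bounds(self, which):
        """Initial/final state pins as (index, lo, hi) triples; scalar pins
        become equal bounds on that endpoint's variables."""
        src = self.state_initial if which == "initial" else self.state_final
        names = self.system.state_names
        out = []
        for nm, val in src.items():
            if nm not in names:
                raise KeyError(f"{which} condition on unknown state {nm!r}")
            lo, hi = (val, val) if np.isscalar(val) else val
            if lo > hi:
                raise ValueError(f"{which} bounds for {nm!r} out of order")
            out.append((names.index(nm), float(lo), float(hi)))
        return out

    @property
    def path_specs(self):
        return self.path_constraints

    def validate(self):
        if not self.goals:
            raise ValueError("problem needs at least one goal")
        for g in self.goals:
            if g.weight < 0:
                raise ValueError("goal weights must be >= 0")
            g.bind(self.system)
            if isinstance(g, FinalTimeGoal):
                g.t0 = self.t0
        for b in self.boundary_specs:
            b.bind(self.system)
        for pc in self.path_constraints:
            pc.bind(self.system)
        lo, hi = self.duration_bounds
        if not (np.isfinite(lo) and np.isfinite(hi)):
            raise ValueError("duration bounds must be finite")
        self.resolved_state_bounds()
        self.resolved_control_bounds()
        self.endpoint_bounds("initial")
        self.endpoint_bounds("final")
        return self


def register_parameter(problem: ProblemDef, path: str, bounds):
    """Declare a scalar model property as a free optimization variable.

    The property must resolve inside the problem's model; the transcribed
    program gains exactly one variable.  The system is rebuilt so the
    dynamics see the parameter symbolically.
    """
    sysold = problem.system
    if not isinstance(sysold, MuscularSystem):
        raise ValueError("parameters require a model-backed system")
    _resolve_parameter(sysold.model, path)  # raises on unknown path
    problem.parameters = list(problem.parameters) + [Parameter(path,
                                                               tuple(bounds))]
    problem.system = MuscularSystem(
        sysold.model, parameters=tuple(p.path for p in problem.parameters))
    return problem


def solve_problem(problem: ProblemDef, config: TranscriptionConfig,
                  guess=None, verbose: int = 0):
    """Transcribe and solve; returns (Solution, NLPStructure).

    ``guess`` may be a raw decision vector, a Trajectory (resampled onto the
    grid), or None (midpoint-of-bounds default).
    """
    from .trajectory import Solution, guess_from_trajectory, solution_from_raw

    nlp = assemble_nlp(problem, config)
    if guess is not None and not isinstance(guess, np.ndarray):
        guess = guess_from_trajectory(nlp, guess)
    raw = solve_nlp(nlp, guess=guess, verbose=verbose)
    return solution_from_raw(nlp, raw), nlp
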