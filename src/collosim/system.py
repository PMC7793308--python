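"""Continuous dynamical systems as consumed by the transcription layer.

A *system* bundles the continuous state derivative, algebraic path residuals,
and kinematic-constraint residuals behind a small vectorized protocol
(:class:`ContinuousSystem`).  Two concrete systems cover the package's scope:

* :class:`MuscularSystem` — the full differential-algebraic dynamics of a
  :class:`~collosim.model.ModelSpec`: multibody dynamics (explicit or
  implicit), muscle activation dynamics, compliant-tendon force states, and
  holonomic constraints with Lagrange multipliers.
* :class:`PrescribedMotionSystem` — the muscle-redundancy ("inverse") system
  in which kinematics are fixed, time-varying data and the remaining states
  are activations and tendon forces; force balance against inverse dynamics
  becomes a path residual.

Anything with the same duck-typed surface (e.g. the analytic steering
benchmark in :mod:`collosim.verify`) can be transcribed the same way.
"""

from __future__ import annotations

import numpy as np

from . import model as md
from . import muscle as mm

__all__ = ["ContinuousSystem", "MuscularSystem", "PrescribedMotionSystem",
           "TENDON_RATE_SCALE"]

#: Normalized tendon-force derivative control is scaled by this factor
#: (d ft/dt = TENDON_RATE_SCALE * control, control in [-1, 1]).
TENDON_RATE_SCALE = 50.0

ACTIVATION_BOUNDS = (0.01, 1.0)


class ContinuousSystem:
    """Protocol for transcribable dynamics.  Subclasses fill the attributes
    and override the methods they support; arrays are vectorized with a
    trailing time axis."""

    state_names: list
    control_names: list
    n_kin: int = 0         # holonomic constraint equations (lambda size)
    n_speeds: int = 0      # generalized-speed count (implicit-mode w size)
    path_names: list = []  # names of equality path residual rows

    def rate(self, x, c, lam, t, p):
        raise NotImplementedError

    def implicit_rate(self, x, c, lam, w, t, p):
        raise NotImplementedError(
            f"{type(self).__name__} does not support implicit dynamics")

    def implicit_residual(self, x, c, lam, w, t, p):
        raise NotImplementedError(
            f"{type(self).__name__} does not support implicit dynamics")

    def path_residuals(self, x, c, lam, t, p):
        return np.zeros((0, np.atleast_2d(x).shape[1]))

    def kin_residuals(self, x, p):
        return (np.zeros((0, np.atleast_2d(x).shape[1])),) * 2

    def qdot_correction(self, x, gamma, p):
        """Velocity-correction term G(q)^T gamma added to the q-rows of the
        state derivative (Hermite-Simpson midpoints only)."""
        return np.zeros_like(np.atleast_2d(x))

    def default_state_bounds(self):
        return {}

    def default_control_bounds(self):
        return {}


def _resolve_parameter(spec: md.ModelSpec, path: str):
    """Classify a model-property path.  Returns ('engine', path) for
    properties that enter the symbolic dynamics, or ('fiso', index) /
    ('gain', index) for runtime numeric overrides."""
    parts = path.split("/")
    if len(parts) != 3:
        raise KeyError(f"malformed parameter path {path!r} "
                       "(expected section/name/field)")
    section, name, fld = parts
    if section == "bodies" and fld == "mass":
        spec.body(name)
        return ("engine", path)
    if section == "springs" and fld == "stiffness":
        if not any(s.coordinate == name for s in spec.springs):
            raise KeyError(f"no torsional spring on coordinate {name!r}")
        return ("engine", path)
    if section == "muscles" and fld == "F_iso":
        for i, m in enumerate(spec.muscles):
            if m.name == name:
                return ("fiso", i)
        raise KeyError(f"no muscle named {name!r}")
    if section == "actuators" and fld == "gain":
        for i, a in enumerate(spec.actuators):
            if a.name == name:
                return ("gain", i)
        raise KeyError(f"no actuator named {name!r}")
    raise KeyError(f"unsupported parameter path {path!r}")


class _ParamMap:
    """Splits the flat NLP parameter vector into engine-symbol values and
    runtime numeric overrides (muscle F_iso scale, actuator gains)."""

    def __init__(self, spec, paths):
        self.paths = tuple(paths)
        self.engine_paths = []
        self._engine_pos = []
        self._fiso = []   # (muscle index, param position)
        self._gain = []   # (actuator index, param position)
        for k, path in enumerate(self.paths):
            kind, ref = _resolve_parameter(spec, path)
            if kind == "engine":
                self._engine_pos.append(k)
                self.engine_paths.append(ref)
            elif kind == "fiso":
                self._fiso.append((ref, k))
            else:
                self._gain.append((ref, k))
        self.spec = spec

    def engine_values(self, p):
        return tuple(np.asarray(p, dtype=float)[self._engine_pos]) \
            if self._engine_pos else ()

    def fiso_scale(self, p):
        if not self._fiso:
            return None
        s = np.ones(len(self.spec.muscles))
        for i, k in self._fiso:
            s[i] = p[k] / self.spec.muscles[i].params.F_iso
        return s

    def act_gain(self, p):
        if not self._gain:
            return None
        return {i: p[k] for i, k in self._gain}


class MuscularSystem(ContinuousSystem):
    """Full continuous dynamics of a planar musculoskeletal model.

    State ordering (documented, fixed): generalized coordinates ``q``,
    generalized speeds ``u`` (``qdot = u``), muscle activations ``a`` in
    [0.01, 1], and normalized tendon forces for compliant-tendon muscles.
    Controls: muscle excitations, coordinate-actuator controls, then one
    scaled tendon-force-rate control per compliant muscle.
    """

    def __init__(self, spec: md.ModelSpec, parameters: tuple = ()):
        self.model = spec
        self.pmap = _ParamMap(spec, parameters)
        self.engine = md.PlanarEngine(spec,
                                      free_params=tuple(self.pmap.engine_paths))
        self.nq = spec.nq
        self.nmus = len(spec.muscles)
        self.nact = len(spec.actuators)
        self.compliant = [i for i, m in enumerate(spec.muscles)
                          if not m.params.rigid_tendon]
        self.nft = len(self.compliant)
        coords = spec.coordinate_names()
        self.state_names = (
            coords + [f"{n}_u" for n in coords]
            + [f"{m.name}_activation" for m in spec.muscles]
            + [f"{spec.muscles[i].name}_tendon_force" for i in self.compliant])
        self.control_names = (
            [f"{m.name}_excitation" for m in spec.muscles]
            + [a.name for a in spec.actuators]
            + [f"{spec.muscles[i].name}_tendon_force_rate"
               for i in self.compliant])
        self.n_kin = self.engine.n_kin
        self.n_speeds = self.nq
        self.path_names = [f"{spec.muscles[i].name}_tendon_equilibrium"
                           for i in self.compliant]

    # ---- state/control unpacking

    def split_state(self, x):
        x = np.atleast_2d(x)
        nq, nm, nf = self.nq, self.nmus, self.nft
        return (x[:nq], x[nq:2 * nq], x[2 * nq:2 * nq + nm],
                x[2 * nq + nm:2 * nq + nm + nf])

    def split_controls(self, c):
        c = np.atleast_2d(c)
        nm, na = self.nmus, self.nact
        return c[:nm], c[nm:nm + na], c[nm + na:]

    # ---- pieces

    def _tau(self, q, u, a, ft, c, lam, p):
        pe = self.pmap.engine_values(p)
        fs = self.pmap.fiso_scale(p)
        gains = self.pmap.act_gain(p)
        A = self.engine._act_map
        if gains:
            A = A.copy()
            for ia, val in gains.items():
                j = self.engine.coord_index[self.model.actuators[ia].coordinate]
                A[j, ia] = val
        return md._total_applied(self.model, self.engine, q, u, a, ft, c,
                                 lam, pe, fiso_scale=fs, act_gain=A)

    def _activation_rate(self, e, a):
        out = np.empty_like(np.atleast_2d(a))
        for i, mus in enumerate(self.model.muscles):
            out[i] = mm.activation_derivative(e[i], a[i], mus.params)
        return out

    def _assemble_xdot(self, q, u, udot, e, a, aux):
        parts = [u, udot]
        if self.nmus:
            parts.append(self._activation_rate(e, a))
        if self.nft:
            parts.append(TENDON_RATE_SCALE * aux)
        return np.concatenate(parts)

    # ---- protocol

    def rate(self, x, c, lam, t, p):
        q, u, a, ft = self.split_state(x)
        e, _, aux = self.split_controls(c)
        tau = self._tau(q, u, a, ft, c, lam, p)
        pe = self.pmap.engine_values(p)
        M = self.engine.mass_matrix(q, pe)
        rhs = (tau - self.engine.bias_force(q, u, pe)).T[..., None]
        udot = np.linalg.solve(M, rhs)[..., 0].T
        return self._assemble_xdot(q, u, udot, e, a, aux)

    def implicit_rate(self, x, c, lam, w, t, p):
        q, u, a, _ = self.split_state(x)
        e, _, aux = self.split_controls(c)
        return self._assemble_xdot(q, u, np.atleast_2d(w), e, a, aux)

    def implicit_residual(self, x, c, lam, w, t, p):
        q, u, a, ft = self.split_state(x)
        tau = self._tau(q, u, a, ft, c, lam, p)
        pe = self.pmap.engine_values(p)
        M = self.engine.mass_matrix(q, pe)
        w = np.atleast_2d(w)
        return (np.einsum("tij,jt->it", M, w)
                + self.engine.bias_force(q, u, pe) - tau)

    def path_residuals(self, x, c, lam, t, p):
        if not self.nft:
            return np.zeros((0, np.atleast_2d(x).shape[1]))
        q, u, a, ft = self.split_state(x)
        _, _, aux = self.split_controls(c)
        pe = self.pmap.engine_values(p)
        L, V, _ = self.engine.muscle_geometry(q, u, pe)
        rows = []
        for k, i in enumerate(self.compliant):
            prm = self.model.muscles[i].params
            rows.append(mm.tendon_equilibrium_residual(
                a[i], L[i], V[i], ft[k], TENDON_RATE_SCALE * aux[k], prm))
        return np.stack(rows)

    def kin_residuals(self, x, p):
        q, u, _, _ = self.split_state(x)
        return self.engine.kin_residuals(q, u, self.pmap.engine_values(p))

    def qdot_correction(self, x, gamma, p):
        q, _, _, _ = self.split_state(x)
        G = self.engine.constraint_jacobian(q, self.pmap.engine_values(p))
        out = np.zeros_like(np.atleast_2d(x))
        out[:self.nq] = np.einsum("tij,it->jt", G, np.atleast_2d(gamma))
        return out

    # ---- bounds

    def default_state_bounds(self):
        b = {}
        for name in self.model.coordinate_names():
            b[name] = tuple(self.model.coordinate(name).bounds)
            b[f"{name}_u"] = (-np.inf, np.inf)
        for m in self.model.muscles:
            b[f"{m.name}_activation"] = ACTIVATION_BOUNDS
        for i in self.compliant:
            b[f"{self.model.muscles[i].name}_tendon_force"] = (0.0, 5.0)
        return b

    def default_control_bounds(self):
        b = {}
        for m in self.model.muscles:
            b[f"{m.name}_excitation"] = ACTIVATION_BOUNDS
        for a in self.model.actuators:
            b[a.name] = (-np.inf, np.inf)
        for i in self.compliant:
            b[f"{self.model.muscles[i].name}_tendon_force_rate"] = (-1.0, 1.0)
        return b


class PrescribedMotionSystem(ContinuousSystem):
    """Muscle redundancy with exactly prescribed kinematics.

    ``q``, ``u`` and ``qdd`` are fixed functions of time (cubic interpolants
    of the provided kinematics and their analytic derivatives).  States are
    muscle activations (and compliant tendon forces); controls are muscle
    excitations, one reserve actuator per coordinate (ideal torque/force,
    bounded), and tendon-force-rate controls.  The force balance

        muscle generalized forces + reserves = inverse dynamics

    is an equality path residual at every collocation point.
    """

    def __init__(self, spec: md.ModelSpec, qfun, ufun, qddfun,
                 reserve_bound: float = 2.5):
        if spec.actuators:
            raise ValueError("prescribed-motion system adds its own reserves;"
                             " model must not declare coordinate actuators")
        self.model = spec
        self.engine = md.PlanarEngine(spec)
        self.qfun, self.ufun, self.qddfun = qfun, ufun, qddfun
        self.nq = spec.nq
        self.nmus = len(spec.muscles)
        self.compliant = [i for i, m in enumerate(spec.muscles)
                          if not m.params.rigid_tendon]
        self.nft = len(self.compliant)
        self.reserve_bound = float(reserve_bound)
        coords = spec.coordinate_names()
        self.state_names = (
            [f"{m.name}_activation" for m in spec.muscles]
            + [f"{spec.muscles[i].name}_tendon_force" for i in self.compliant])
        self.control_names = (
            [f"{m.name}_excitation" for m in spec.muscles]
            + [f"reserve_{n}" for n in coords]
            + [f"{spec.muscles[i].name}_tendon_force_rate"
               for i in self.compliant])
        self.path_names = (
            [f"force_balance_{n}" for n in coords]
            + [f"{spec.muscles[i].name}_tendon_equilibrium"
               for i in self.compliant])

    def split_state(self, x):
        x = np.atleast_2d(x)
        return x[:self.nmus], x[self.nmus:self.nmus + self.nft]

    def split_controls(self, c):
        c = np.atleast_2d(c)
        nm, nq = self.nmus, self.nq
        return c[:nm], c[nm:nm + nq], c[nm + nq:]

    def rate(self, x, c, lam, t, p):
        a, _ = self.split_state(x)
        e, _, aux = self.split_controls(c)
        parts = []
        if self.nmus:
            out = np.empty_like(a)
            for i, mus in enumerate(self.model.muscles):
                out[i] = mm.activation_derivative(e[i], a[i], mus.params)
            parts.append(out)
        if self.nft:
            parts.append(TENDON_RATE_SCALE * aux)
        return np.concatenate(parts) if parts else np.zeros_like(x)

    def path_residuals(self, x, c, lam, t, p):
        a, ft = self.split_state(x)
        e, res, aux = self.split_controls(c)
        t = np.atleast_1d(t)
        q, u, qdd = self.qfun(t), self.ufun(t), self.qddfun(t)
        required = md.inverse_dynamics(self.model, q, u, qdd)
        F = md._muscle_forces(self.model, self.engine, q, u, a, ft)
        _, _, arms = self.engine.muscle_geometry(q, u)
        supplied = np.einsum("tmj,mt->jt", arms, F) + res
        rows = [supplied - required]
        if self.nft:
            L, V, _ = self.engine.muscle_geometry(q, u)
            for k, i in enumerate(self.compliant):
                prm = self.model.muscles[i].params
                rows.append(np.atleast_2d(mm.tendon_equilibrium_residual(
                    a[i], L[i], V[i], ft[k], TENDON_RATE_SCALE * aux[k],
                    prm)))
        return np.concatenate(rows)

    def default_state_bounds(self):
        b = {f"{m.name}_activation": ACTIVATION_BOUNDS
             for m in self.model.muscles}
        for i in self.compliant:
            b[f"{self.model.muscles[i].name}_tendon_force"] = (0.0, 5.0)
        return b

    def default_control_bounds(self):
        b = {f"{m.name}_excitation": ACTIVATION_BOUNDS
             for m in self.model.muscles}
        rb = self.reserve_bound
        for n in self.model.coordinate_names():
            b[f"reserve_{n}"] = (-rb, rb) if np.isfinite(rb) \
                else (-np.inf, np.inf)
        for i in self.compliant:
            b[f"{self.model.muscles[i].name}_tendon_force_rate"] = (-1.0, 1.0)
        return b
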