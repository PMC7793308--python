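"""Planar multibody models and their dynamics.

A model is a tree of rigid bodies connected by pin, slider, weld, or
free-planar joints, optionally augmented with explicit holonomic constraints
(point coincidence for loop closure, linear coordinate coupling).  Forces come
from gravity, straight-line muscle paths (Hill-type, :mod:`collosim.muscle`),
torsional springs, smooth sphere/half-space contact, and ideal coordinate
actuators.  Kinematic constraints enter the dynamics through Lagrange
multipliers.

The equations of motion are derived symbolically (sympy) from the Lagrangian
of the declared tree, then lambdified to vectorized numpy callables.  This
keeps the dynamics exact (no hand-derived per-model code, no finite
differencing of the model itself) while remaining fast enough for collocation
residual evaluation over a full time grid.

Conventions: SI units, radians, y is up, gravity default (0, -9.80665) m/s^2.
State ordering is fixed as q-block, u-block, activation-block, tendon-force
block (documented on :class:`ContinuousState`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import sympy as sp

from .muscle import MuscleParams, tendon_force

__all__ = [
    "Coordinate", "Body", "Joint", "PathPoint", "Muscle", "TorsionalSpring",
    "ContactElement", "CoordinateActuator", "CoordinateCoupler",
    "PointCoincidence", "ModelSpec", "ContinuousState", "PlanarEngine",
    "contact_force", "applied_generalized_forces", "forward_dynamics",
    "inverse_dynamics", "constraint_eval", "joint_reaction_load",
    "path_kinematics", "total_energy",
]

GRAVITY_DEFAULT = (0.0, -9.80665)


# -- specification dataclasses ------------------------------------------------

@dataclass
class Coordinate:
    name: str
    unit: str = "rad"          # 'rad' | 'm'
    bounds: tuple = (-math.inf, math.inf)


@dataclass
class Body:
    name: str
    mass: float
    inertia: float = 0.0       # about COM, kg m^2
    com: tuple = (0.0, 0.0)    # COM location in the body frame


@dataclass
class Joint:
    """Connection of ``child`` to ``parent`` (a body name or ``"ground"``).

    kind:
      * ``pin`` — one rotational coordinate about coincident points
        (``parent_point`` in the parent frame, ``child_point`` in the child).
      * ``slider`` — one translational coordinate along ``axis`` (parent
        frame).
      * ``weld`` — no coordinates.
      * ``free_planar`` — x/y translation (plus rotation iff the body has
        nonzero inertia).
    """
    kind: str
    child: str
    parent: str = "ground"
    parent_point: tuple = (0.0, 0.0)
    child_point: tuple = (0.0, 0.0)
    axis: tuple = (1.0, 0.0)
    coordinates: list = field(default_factory=list)


@dataclass
class PathPoint:
    body: str                  # body name or 'ground'
    location: tuple            # point in that body's frame


@dataclass
class Muscle:
    params: MuscleParams
    path: list = field(default_factory=list)   # list[PathPoint], >= 2

    @property
    def name(self):
        return self.params.name


@dataclass
class TorsionalSpring:
    coordinate: str
    stiffness: float           # N m / rad
    equilibrium: float = 0.0   # rad


@dataclass
class ContactElement:
    name: str
    body: str
    location: tuple            # sphere center in the body frame
    radius: float
    stiffness: float           # k_c, N/m^(3/2)
    dissipation: float = 1.0   # c_d, s/m
    friction: float = 0.0      # mu
    smoothing: float = 1e-4    # eps, m  (depth smoothing)
    vel_smoothing: float = 0.05  # v_s, m/s (tanh friction scale)


@dataclass
class CoordinateActuator:
    name: str
    coordinate: str
    gain: float = 1.0          # generalized force per unit control


@dataclass
class CoordinateCoupler:
    """Holonomic coupling ``q_dependent - c * q_independent - offset = 0``."""
    dependent: str
    independent: str
    ratio: float
    offset: float = 0.0


@dataclass
class PointCoincidence:
    """Loop-closure constraint: a point on body_a coincides with one on
    body_b (two scalar equations)."""
    body_a: str
    point_a: tuple
    body_b: str
    point_b: tuple


@dataclass
class ModelSpec:
    name: str = "model"
    gravity: tuple = GRAVITY_DEFAULT
    bodies: list = field(default_factory=list)
    joints: list = field(default_factory=list)
    muscles: list = field(default_factory=list)
    springs: list = field(default_factory=list)
    contacts: list = field(default_factory=list)
    actuators: list = field(default_factory=list)
    constraints: list = field(default_factory=list)  # couplers/coincidence

    # ---- bookkeeping

    def coordinate_names(self):
        names = []
        for j in self.joints:
            names.extend(c.name for c in j.coordinates)
        return names

    @property
    def nq(self):
        return len(self.coordinate_names())

    def coordinate(self, name):
        for j in self.joints:
            for c in j.coordinates:
                if c.name == name:
                    return c
        raise KeyError(f"unknown coordinate {name!r} in model {self.name!r}")

    def body(self, name):
        for b in self.bodies:
            if b.name == name:
                return b
        raise KeyError(f"unknown body {name!r} in model {self.name!r}")

    def n_constraint_equations(self):
        m = 0
        for c in self.constraints:
            m += 2 if isinstance(c, PointCoincidence) else 1
        return m

    def validate(self):
        for b in self.bodies:
            if b.mass <= 0:
                raise ValueError(f"body {b.name!r}: mass must be > 0")
            if b.inertia < 0:
                raise ValueError(f"body {b.name!r}: inertia must be >= 0")
        names = self.coordinate_names()
        if len(set(names)) != len(names):
            raise ValueError("duplicate coordinate names")
        m = self.n_constraint_equations()
        if m and m >= self.nq:
            raise ValueError(
                f"{m} constraint equations must be fewer than "
                f"{self.nq} coordinates")
        for mus in self.muscles:
            if len(mus.path) < 2:
                raise ValueError(
                    f"muscle {mus.name!r}: path needs >= 2 points")
        # path lengths positive on a coarse grid of bounded coordinates
        engine = PlanarEngine(self)
        if self.muscles:
            grids = []
            for nm in names:
                lo, hi = self.coordinate(nm).bounds
                if math.isfinite(lo) and math.isfinite(hi):
                    grids.append(np.linspace(lo, hi, 3))
                else:
                    grids.append(np.array([0.0]))
            mesh = np.meshgrid(*grids, indexing="ij")
            q = np.stack([g.ravel() for g in mesh])
            lengths, _, _ = engine.muscle_geometry(q, np.zeros_like(q))
            if np.any(lengths <= 0):
                raise ValueError("muscle path length not positive over the "
                                 "coordinate bounds")
        return self


@dataclass
class ContinuousState:
    """Continuous state with fixed block ordering.

    The flat layout used everywhere (collocation, shooting, trajectories) is
    ``[q (nq), u (nq), a (n_muscles), ft (n_compliant_tendons)]``.
    """
    q: np.ndarray
    u: np.ndarray
    a: np.ndarray = field(default_factory=lambda: np.zeros(0))
    ft: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self):
        self.q = np.atleast_1d(np.asarray(self.q, dtype=float))
        self.u = np.atleast_1d(np.asarray(self.u, dtype=float))
        self.a = np.atleast_1d(np.asarray(self.a, dtype=float))
        self.ft = np.atleast_1d(np.asarray(self.ft, dtype=float))
        if self.q.shape != self.u.shape:
            raise ValueError("state blocks q and u must have equal length "
                             f"(got {self.q.shape} vs {self.u.shape})")


# -- smooth contact -----------------------------------------------------------

def contact_force(element: ContactElement, depth, v_normal, v_tangent):
    """Smooth sphere/half-space contact force, world components.

    ``depth`` is penetration (positive inside the ground), ``v_normal`` the
    penetration rate, ``v_tangent`` the sliding velocity.  The normal
    component is a Hertz-like power law on a smoothed depth
    ``d_s = (d + sqrt(d^2 + eps^2))/2`` with Hunt-Crossley dissipation; the
    tangential component is a regularized Coulomb friction via tanh.  The
    force is C^1 in all arguments for any real depth.  Returns
    ``(f_tangent, f_normal, torque=0)``.
    """
    d = np.asarray(depth, dtype=float)
    vn = np.asarray(v_normal, dtype=float)
    vt = np.asarray(v_tangent, dtype=float)
    eps = element.smoothing
    ds = 0.5 * (d + np.sqrt(d * d + eps * eps))
    fn = element.stiffness * ds ** 1.5 * (1.0 + 1.5 * element.dissipation * vn)
    ft = -element.friction * fn * np.tanh(vt / element.vel_smoothing)
    return np.stack([ft, fn, np.zeros_like(fn)])


# -- symbolic engine ----------------------------------------------------------

def _rot(angle):
    c, s = sp.cos(angle), sp.sin(angle)
    return sp.Matrix([[c, -s], [s, c]])


class _VecFn:
    """Lambdified sympy column vector, evaluated entrywise, output (r, T)."""

    def __init__(self, args, vec):
        self.r = vec.shape[0]
        self._fns = [sp.lambdify(args, vec[i], modules="numpy")
                     for i in range(self.r)]

    def __call__(self, *cols):
        T = np.broadcast(*[np.asarray(c) for c in cols]).shape if cols else ()
        T = T if T else (1,)
        out = np.empty((self.r,) + T)
        for i, f in enumerate(self._fns):
            out[i] = np.broadcast_to(f(*cols), T)
        return out


class _MatFn:
    """Lambdified sympy matrix, output (T, r, c) for batched linalg."""

    def __init__(self, args, mat):
        self.r, self.c = mat.shape
        self._fns = [[sp.lambdify(args, mat[i, j], modules="numpy")
                      for j in range(self.c)] for i in range(self.r)]

    def __call__(self, *cols):
        T = np.broadcast(*[np.asarray(c) for c in cols]).shape if cols else ()
        T = T if T else (1,)
        out = np.empty(T + (self.r, self.c))
        for i in range(self.r):
            for j in range(self.c):
                out[..., i, j] = np.broadcast_to(self._fns[i][j](*cols), T)
        return out


class _ScalarFn:
    def __init__(self, args, expr):
        self._f = sp.lambdify(args, expr, modules="numpy")

    def __call__(self, *cols):
        T = np.broadcast(*[np.asarray(c) for c in cols]).shape if cols else ()
        T = T if T else (1,)
        return np.broadcast_to(self._f(*cols), T)


class PlanarEngine:
    """Symbolically derived dynamics of one :class:`ModelSpec`.

    Builds, once, the mass matrix M(q), velocity bias c(q,u), generalized
    gravity and spring forces, muscle path geometry (lengths, velocities,
    moment arms), holonomic constraint residuals phi(q) with Jacobian G and
    velocity bias, and per-body/per-point kinematic Jacobians.  All evaluators
    are vectorized over a trailing time axis: coordinate inputs have shape
    ``(nq, T)``.

    ``free_params`` maps property paths (``"bodies/<name>/mass"``,
    ``"springs/<coordinate>/stiffness"``) to positions in a parameter vector
    appended to every evaluator call.
    """

    SYMBOLIC_PARAM_SECTIONS = ("bodies", "springs")

    def __init__(self, spec: ModelSpec, free_params: tuple = ()):
        self.spec = spec
        self.free_params = tuple(free_params)
        self.nq = spec.nq
        qn = spec.coordinate_names()
        self._qs = list(sp.symbols([f"q_{n}" for n in qn])) if qn else []
        self._us = list(sp.symbols([f"u_{n}" for n in qn])) if qn else []
        self._ps = [sp.Symbol(f"par{i}") for i in range(len(self.free_params))]
        self._param_of = dict(zip(self.free_params, self._ps))
        self._args = tuple(self._qs) + tuple(self._us) + tuple(self._ps)
        self._build()

    # ---- property substitution

    def _prop(self, path, value):
        return self._param_of.get(path, sp.Float(value))

    # ---- symbolic construction

    def _build(self):
        spec = self.spec
        qs, us = self._qs, self._us
        coord_index = {n: i for i, n in enumerate(spec.coordinate_names())}
        self.coord_index = coord_index

        frames = {"ground": (sp.Integer(0), sp.Matrix([0, 0]))}
        k = 0
        self._joint_of_body = {}
        for joint in spec.joints:
            if joint.parent not in frames:
                raise ValueError(
                    f"joint for body {joint.child!r}: parent "
                    f"{joint.parent!r} not yet defined (declare parents "
                    "first)")
            pa, po = frames[joint.parent]
            pp = sp.Matrix(joint.parent_point)
            cp = sp.Matrix(joint.child_point)
            ncoord = len(joint.coordinates)
            if joint.kind == "pin":
                if ncoord != 1:
                    raise ValueError("pin joint needs exactly 1 coordinate")
                th = qs[k]
                ca = pa + th
                co = po + _rot(pa) * pp - _rot(ca) * cp
                k += 1
            elif joint.kind == "slider":
                if ncoord != 1:
                    raise ValueError("slider joint needs exactly 1 coordinate")
                s = qs[k]
                ax = sp.Matrix(joint.axis)
                ca = pa
                co = po + _rot(pa) * (pp + s * ax) - _rot(ca) * cp
                k += 1
            elif joint.kind == "weld":
                if ncoord != 0:
                    raise ValueError("weld joint has no coordinates")
                ca = pa
                co = po + _rot(pa) * pp - _rot(ca) * cp
            elif joint.kind == "free_planar":
                body = spec.body(joint.child)
                want = 3 if body.inertia > 0 else 2
                if ncoord != want:
                    raise ValueError(
                        f"free_planar joint on {joint.child!r} needs "
                        f"{want} coordinates (x, y{', theta' if want == 3 else ''})")
                x, y = qs[k], qs[k + 1]
                th = qs[k + 2] if want == 3 else sp.Integer(0)
                ca = pa + th
                co = po + _rot(pa) * sp.Matrix([x, y])
                k += want
            else:
                raise ValueError(f"unknown joint kind {joint.kind!r}")
            frames[joint.child] = (ca, co)
            self._joint_of_body[joint.child] = joint
        if k != self.nq:
            raise ValueError("coordinate bookkeeping mismatch")
        self._frames = frames

        qcol = sp.Matrix(qs) if qs else sp.Matrix.zeros(0, 1)
        ucol = sp.Matrix(us) if us else sp.Matrix.zeros(0, 1)
        g = sp.Matrix(spec.gravity)

        # kinetic / potential energy
        T = sp.Integer(0)
        V = sp.Integer(0)
        self._com_expr = {}
        for b in spec.bodies:
            ang, org = frames[b.name]
            com_w = org + _rot(ang) * sp.Matrix(b.com)
            self._com_expr[b.name] = com_w
            mass = self._prop(f"bodies/{b.name}/mass", b.mass)
            Jb = com_w.jacobian(qcol) if self.nq else sp.Matrix.zeros(2, 0)
            v = Jb * ucol
            w = (sp.Matrix([ang]).jacobian(qcol) * ucol)[0] if self.nq else 0
            T = T + mass * (v.T * v)[0] / 2 + sp.Float(b.inertia) * w ** 2 / 2
            V = V - mass * (g.T * com_w)[0]
        T = sp.expand(T)

        M = sp.Matrix([[sp.diff(T, ui, uj) for uj in us] for ui in us]) \
            if self.nq else sp.Matrix.zeros(0, 0)
        Mu = M * ucol
        bias = (Mu.jacobian(qcol) * ucol
                - sp.Matrix([sp.diff(T, qi) for qi in qs])) \
            if self.nq else sp.Matrix.zeros(0, 1)
        ggen = sp.Matrix([-sp.diff(V, qi) for qi in qs]) \
            if self.nq else sp.Matrix.zeros(0, 1)

        # torsional springs
        spr = sp.Matrix.zeros(self.nq, 1)
        for s in spec.springs:
            i = coord_index[s.coordinate]
            kk = self._prop(f"springs/{s.coordinate}/stiffness", s.stiffness)
            spr[i] = spr[i] - kk * (qs[i] - sp.Float(s.equilibrium))

        # muscle geometry
        self.muscle_names = [m.name for m in spec.muscles]
        nmus = len(spec.muscles)
        lengths = sp.Matrix.zeros(nmus, 1)
        for im, mus in enumerate(spec.muscles):
            pts = []
            for pt in mus.path:
                if pt.body == "ground":
                    pts.append(sp.Matrix(pt.location))
                else:
                    ang, org = frames[pt.body]
                    pts.append(org + _rot(ang) * sp.Matrix(pt.location))
            L = sp.Integer(0)
            for p0, p1 in zip(pts[:-1], pts[1:]):
                d = p1 - p0
                L = L + sp.sqrt((d.T * d)[0])
            lengths[im] = L
        dldq = lengths.jacobian(qcol) if self.nq else sp.Matrix.zeros(nmus, 0)
        lvel = dldq * ucol

        # holonomic constraints
        rows = []
        for c in spec.constraints:
            if isinstance(c, CoordinateCoupler):
                rows.append(qs[coord_index[c.dependent]]
                            - sp.Float(c.ratio) * qs[coord_index[c.independent]]
                            - sp.Float(c.offset))
            elif isinstance(c, PointCoincidence):
                def world(body, loc):
                    if body == "ground":
                        return sp.Matrix(loc)
                    ang, org = frames[body]
                    return org + _rot(ang) * sp.Matrix(loc)
                d = world(c.body_a, c.point_a) - world(c.body_b, c.point_b)
                rows.extend([d[0], d[1]])
            else:
                raise ValueError(f"unknown constraint type {type(c).__name__}")
        phi = sp.Matrix(rows) if rows else sp.Matrix.zeros(0, 1)
        self.n_kin = phi.shape[0]
        G = phi.jacobian(qcol) if rows and self.nq else \
            sp.Matrix.zeros(self.n_kin, self.nq)
        Gu = G * ucol if rows else sp.Matrix.zeros(0, 1)
        Gdotu = Gu.jacobian(qcol) * ucol if rows else sp.Matrix.zeros(0, 1)

        args = self._args
        self._M = _MatFn(args, M)
        self._bias = _VecFn(args, bias)
        self._gravity = _VecFn(args, ggen)
        self._spring = _VecFn(args, spr)
        self._lengths = _VecFn(args, lengths) if nmus else None
        self._lvel = _VecFn(args, lvel) if nmus else None
        self._dldq = _MatFn(args, dldq) if nmus else None
        self._phi = _VecFn(args, phi) if rows else None
        self._G = _MatFn(args, G) if rows else None
        self._Gu = _VecFn(args, Gu) if rows else None
        self._Gdotu = _VecFn(args, Gdotu) if rows else None
        self._energy = _ScalarFn(args, T + V)

        # actuator mapping (constant)
        A = np.zeros((self.nq, len(spec.actuators)))
        for ia, act in enumerate(spec.actuators):
            A[coord_index[act.coordinate], ia] = act.gain
        self._act_map = A

        # point-kinematics caches for contact / joint reaction
        self._point_fns = {}
        self._com_fns = {}

    # ---- evaluation helpers

    def _cols(self, q, u, p):
        q = np.atleast_2d(np.asarray(q, dtype=float))
        u = np.atleast_2d(np.asarray(u, dtype=float))
        p = tuple(np.asarray(p, dtype=float)) if len(self.free_params) else ()
        return tuple(q) + tuple(u) + tuple(p)

    def mass_matrix(self, q, p=()):
        u = np.zeros_like(np.atleast_2d(q))
        return self._M(*self._cols(q, u, p))

    def bias_force(self, q, u, p=()):
        return self._bias(*self._cols(q, u, p))

    def gravity_force(self, q, p=()):
        u = np.zeros_like(np.atleast_2d(q))
        return self._gravity(*self._cols(q, u, p))

    def spring_force(self, q, p=()):
        u = np.zeros_like(np.atleast_2d(q))
        return self._spring(*self._cols(q, u, p))

    def muscle_geometry(self, q, u, p=()):
        """(lengths (nmus,T), velocities (nmus,T), moment arms (T,nmus,nq))."""
        if not self.muscle_names:
            T = np.atleast_2d(q).shape[1]
            return (np.zeros((0, T)), np.zeros((0, T)),
                    np.zeros((T, 0, self.nq)))
        cols = self._cols(q, u, p)
        return self._lengths(*cols), self._lvel(*cols), -self._dldq(*cols)

    def kin_residuals(self, q, u, p=()):
        """(phi (m,T), G u (m,T)) — position and velocity level residuals."""
        if not self.n_kin:
            T = np.atleast_2d(q).shape[1]
            return np.zeros((0, T)), np.zeros((0, T))
        cols = self._cols(q, u, p)
        return self._phi(*cols), self._Gu(*cols)

    def constraint_jacobian(self, q, p=()):
        if not self.n_kin:
            return np.zeros((np.atleast_2d(q).shape[1], 0, self.nq))
        u = np.zeros_like(np.atleast_2d(q))
        return self._G(*self._cols(q, u, p))

    def constraint_velocity_bias(self, q, u, p=()):
        if not self.n_kin:
            return np.zeros((0, np.atleast_2d(q).shape[1]))
        return self._Gdotu(*self._cols(q, u, p))

    def energy(self, q, u, p=()):
        return self._energy(*self._cols(q, u, p))

    # ---- point kinematics (lazily derived per point)

    def _point_kin(self, body, location):
        key = (body, tuple(location))
        if key not in self._point_fns:
            if body == "ground":
                pos = sp.Matrix(location)
            else:
                ang, org = self._frames[body]
                pos = org + _rot(ang) * sp.Matrix(location)
            qcol = sp.Matrix(self._qs) if self.nq else sp.Matrix.zeros(0, 1)
            ucol = sp.Matrix(self._us) if self.nq else sp.Matrix.zeros(0, 1)
            J = pos.jacobian(qcol) if self.nq else sp.Matrix.zeros(2, 0)
            vel = J * ucol
            jdotu = vel.jacobian(qcol) * ucol if self.nq \
                else sp.Matrix.zeros(2, 1)
            self._point_fns[key] = (_VecFn(self._args, pos),
                                    _VecFn(self._args, vel),
                                    _MatFn(self._args, J),
                                    _VecFn(self._args, jdotu))
        return self._point_fns[key]

    def point_kinematics(self, body, location, q, u, p=()):
        """Position, velocity, Jacobian, and J̇u of a body-fixed point."""
        fns = self._point_kin(body, location)
        cols = self._cols(q, u, p)
        return tuple(f(*cols) for f in fns)

    def body_angle(self, body, q, p=()):
        if body == "ground":
            return np.zeros(np.atleast_2d(q).shape[1])
        ang, _ = self._frames[body]
        if body not in self._com_fns:
            self._com_fns[body] = _ScalarFn(self._args, ang)
        u = np.zeros_like(np.atleast_2d(q))
        return self._com_fns[body](*self._cols(q, u, p))

    def descendants(self, body):
        """The body and every body attached below it in the tree."""
        out = {body}
        changed = True
        while changed:
            changed = False
            for j in self.spec.joints:
                if j.parent in out and j.child not in out:
                    out.add(j.child)
                    changed = True
        return out


# -- internal numeric force assembly -----------------------------------------

def _muscle_forces(spec, engine, q, u, a, ft, p=(), fiso_scale=None):
    """Tension of every muscle, shape (nmus, T)."""
    lengths, vels, _ = engine.muscle_geometry(q, u, p)
    out = np.zeros_like(lengths)
    i_ft = 0
    for i, mus in enumerate(spec.muscles):
        prm = mus.params
        if not prm.rigid_tendon:
            f = tendon_force(a[i], lengths[i], vels[i], prm,
                             ft_tilde=ft[i_ft], validate=False)
            i_ft += 1
        else:
            f = tendon_force(a[i], lengths[i], vels[i], prm, validate=False)
        if fiso_scale is not None:
            f = f * fiso_scale[i]
        out[i] = f
    return out


def _contact_generalized(spec, engine, q, u, p=()):
    nq = engine.nq
    T = np.atleast_2d(q).shape[1]
    tau = np.zeros((nq, T))
    for el in spec.contacts:
        pos, vel, J, _ = engine.point_kinematics(el.body, el.location, q, u, p)
        depth = el.radius - pos[1]
        f = contact_force(el, depth, -vel[1], vel[0])
        tau += np.einsum("tij,it->jt", J, f[:2])
    return tau


def _total_applied(spec, engine, q, u, a, ft, controls, lam, p=(),
                   fiso_scale=None, act_gain=None):
    """All generalized forces except inertial/bias: gravity, springs,
    contact, muscles, coordinate actuators, and G^T lambda."""
    nmus = len(spec.muscles)
    tau = engine.gravity_force(q, p) + engine.spring_force(q, p)
    if spec.contacts:
        tau = tau + _contact_generalized(spec, engine, q, u, p)
    if nmus:
        F = _muscle_forces(spec, engine, q, u, a, ft, p, fiso_scale)
        _, _, arms = engine.muscle_geometry(q, u, p)
        tau = tau + np.einsum("tmj,mt->jt", arms, F)
    nact = len(spec.actuators)
    if nact:
        act = np.atleast_2d(controls)[nmus:nmus + nact]
        A = engine._act_map if act_gain is None else act_gain
        tau = tau + A @ act
    if engine.n_kin:
        G = engine.constraint_jacobian(q, p)
        lam = np.atleast_2d(lam)
        tau = tau + np.einsum("tij,it->jt", G, lam)
    return tau


# -- public operations --------------------------------------------------------

def _as_rows(arr):
    """1-D input is one time sample: orient it as a column of rows."""
    a = np.asarray(arr, dtype=float)
    return a[:, None] if a.ndim == 1 else a


def _engine_for(model):
    eng = getattr(model, "_engine_cache", None)
    if eng is None:
        eng = PlanarEngine(model)
        object.__setattr__(model, "_engine_cache", eng)
    return eng


def _split_state(model, state: ContinuousState):
    n_ft = sum(0 if m.params.rigid_tendon else 1 for m in model.muscles)
    nmus = len(model.muscles)
    if state.a.size not in (nmus,) and nmus:
        raise ValueError(
            f"activation block has {state.a.size} entries, model "
            f"{model.name!r} has {nmus} muscles")
    if n_ft and state.ft.size != n_ft:
        raise ValueError(
            f"tendon-force block has {state.ft.size} entries, model needs "
            f"{n_ft}")
    q = state.q.reshape(model.nq, -1)
    u = state.u.reshape(model.nq, -1)
    a = state.a.reshape(nmus, -1) if nmus else np.zeros((0, q.shape[1]))
    ft = state.ft.reshape(n_ft, -1) if n_ft else np.zeros((0, q.shape[1]))
    return q, u, a, ft


def applied_generalized_forces(model: ModelSpec, state: ContinuousState,
                               controls=None, multipliers=None):
    """Sum of all applied generalized forces tau (gravity, muscles mapped
    through moment arms, torsional springs, contact, coordinate actuators,
    and the constraint coupling G(q)^T lambda).

    ``controls`` is ordered (muscle excitations..., actuator controls...);
    only the actuator block enters here (excitations act through states).
    """
    eng = _engine_for(model)
    q, u, a, ft = _split_state(model, state)
    nmus, nact = len(model.muscles), len(model.actuators)
    c = np.zeros((nmus + nact, q.shape[1])) if controls is None \
        else _as_rows(controls)
    if c.shape[0] != nmus + nact:
        raise ValueError(
            f"control block has {c.shape[0]} rows; model {model.name!r} "
            f"expects {nmus} muscle excitations + {nact} actuator controls")
    lam = np.zeros((eng.n_kin, q.shape[1])) if multipliers is None \
        else _as_rows(multipliers)
    if lam.shape[0] != eng.n_kin:
        raise ValueError(
            f"multiplier block has {lam.shape[0]} rows; model declares "
            f"{eng.n_kin} constraint equations")
    tau = _total_applied(model, eng, q, u, a, ft, c, lam)
    return tau[:, 0] if state.q.ndim == 1 else tau


def forward_dynamics(model: ModelSpec, state: ContinuousState, tau,
                     stabilization: float = 0.0):
    """Accelerations (and multipliers) from applied generalized forces.

    Unconstrained: ``qdd = M^-1 (tau - bias)``.  With holonomic constraints
    the KKT system ``[M G^T; G 0][qdd; -lambda] = [tau - bias; -(Gdot u +
    stabilization terms)]`` is solved; ``stabilization`` adds Baumgarte-style
    feedback ``2*s*G u + s^2*phi`` (default off).
    """
    eng = _engine_for(model)
    q, u, _, _ = _split_state(model, state)
    T = q.shape[1]
    tau = np.asarray(tau, dtype=float).reshape(model.nq, -1)
    M = eng.mass_matrix(q)
    rhs = tau - eng.bias_force(q, u)
    if not eng.n_kin:
        try:
            qdd = np.linalg.solve(M, rhs.T[..., None])[..., 0].T
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                f"singular mass matrix at q = {q[:, 0]}")
        lam = np.zeros((0, T))
    else:
        m = eng.n_kin
        G = eng.constraint_jacobian(q)
        gd = eng.constraint_velocity_bias(q, u)
        if stabilization:
            phi, Gu = eng.kin_residuals(q, u)
            gd = gd + 2 * stabilization * Gu + stabilization ** 2 * phi
        n = model.nq
        KKT = np.zeros((T, n + m, n + m))
        KKT[:, :n, :n] = M
        KKT[:, :n, n:] = np.transpose(G, (0, 2, 1))
        KKT[:, n:, :n] = G
        b = np.concatenate([rhs, -gd]).T[..., None]
        try:
            sol = np.linalg.solve(KKT, b)[..., 0].T
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                f"singular KKT matrix at q = {q[:, 0]}")
        qdd, lam = sol[:n], -sol[n:]
    if state.q.ndim == 1:
        return qdd[:, 0], lam[:, 0]
    return qdd, lam


def inverse_dynamics(model: ModelSpec, q, u, qdd):
    """Generalized forces the actuators/muscles must supply:
    ``M(q) qdd + bias(q, u)`` net of gravity, springs, and contact."""
    eng = _engine_for(model)
    q2 = np.asarray(q, dtype=float).reshape(model.nq, -1)
    u2 = np.asarray(u, dtype=float).reshape(model.nq, -1)
    a2 = np.asarray(qdd, dtype=float).reshape(model.nq, -1)
    M = eng.mass_matrix(q2)
    tau = (np.einsum("tij,jt->it", M, a2) + eng.bias_force(q2, u2)
           - eng.gravity_force(q2) - eng.spring_force(q2))
    if model.contacts:
        tau = tau - _contact_generalized(model, eng, q2, u2)
    return tau.reshape(np.asarray(q, dtype=float).shape)


def constraint_eval(model: ModelSpec, q, u):
    """Holonomic constraint residuals: (phi, G, Gdot*u)."""
    eng = _engine_for(model)
    if not eng.n_kin:
        raise ValueError(f"model {model.name!r} declares no kinematic "
                         "constraints")
    q2 = np.asarray(q, dtype=float).reshape(model.nq, -1)
    u2 = np.asarray(u, dtype=float).reshape(model.nq, -1)
    phi, _ = eng.kin_residuals(q2, u2)
    G = eng.constraint_jacobian(q2)
    gd = eng.constraint_velocity_bias(q2, u2)
    if np.asarray(q).ndim == 1:
        return phi[:, 0], G[0], gd[:, 0]
    return phi, G, gd


def joint_reaction_load(model: ModelSpec, state: ContinuousState,
                        controls=None, multipliers=None, joint_child=None,
                        frame: str = "child"):
    """Reaction force at the joint whose child body is ``joint_child``.

    Computed from the Newton force balance of the subtree distal to the
    joint: ``sum_b m_b (a_b - g)`` minus external (muscle, contact) forces
    applied to subtree bodies.  Expressed in the child-body frame by default
    (``frame='world'`` for world axes).  Force components only.
    """
    eng = _engine_for(model)
    if joint_child is None or joint_child not in eng._joint_of_body:
        raise KeyError(f"unknown joint (child body {joint_child!r}) in "
                       f"model {model.name!r}")
    q, u, a, ft = _split_state(model, state)
    T = q.shape[1]
    nmus, nact = len(model.muscles), len(model.actuators)
    c = np.zeros((nmus + nact, T)) if controls is None \
        else _as_rows(controls)
    lam = None if multipliers is None else _as_rows(multipliers)
    if lam is not None or eng.n_kin == 0:
        # multipliers supplied (or none exist): accelerations follow from the
        # unconstrained force balance with G^T lambda as an applied force
        tau = _total_applied(model, eng, q, u, a, ft, c,
                             lam if lam is not None
                             else np.zeros((0, T)))
        M = eng.mass_matrix(q)
        rhs = (tau - eng.bias_force(q, u)).T[..., None]
        qdd = np.linalg.solve(M, rhs)[..., 0].T
    else:
        tau = _total_applied(model, eng, q, u, a, ft, c,
                             np.zeros((eng.n_kin, T)))
        # strip the zero-lambda coupling term; KKT solve finds lambda itself
        qdd, _ = forward_dynamics(
            model, ContinuousState(q, u,
                                   a if nmus else np.zeros((0, T)), ft), tau)
    qdd = qdd.reshape(model.nq, -1)

    subtree = eng.descendants(joint_child)
    g = np.asarray(model.gravity, dtype=float)[:, None]
    F = np.zeros((2, T))
    for b in model.bodies:
        if b.name not in subtree:
            continue
        _, _, J, jdu = eng.point_kinematics(b.name, tuple(b.com), q, u)
        acc = np.einsum("tij,jt->it", J, qdd) + jdu
        F += b.mass * (acc - g)
    # external muscle forces on subtree bodies
    if nmus:
        tension = _muscle_forces(model, eng, q, u, a, ft)
        for im, mus in enumerate(model.muscles):
            pts = [eng.point_kinematics(pt.body, tuple(pt.location), q, u)[0]
                   for pt in mus.path]
            for ip, pt in enumerate(mus.path):
                if pt.body not in subtree:
                    continue
                here = pts[ip]
                for nb in (ip - 1, ip + 1):
                    if 0 <= nb < len(pts):
                        d = pts[nb] - here
                        norm = np.linalg.norm(d, axis=0)
                        F -= tension[im] * d / norm
    for el in model.contacts:
        if el.body in subtree:
            pos, vel, _, _ = eng.point_kinematics(el.body, el.location, q, u)
            f = contact_force(el, el.radius - pos[1], -vel[1], vel[0])
            F -= f[:2]
    if frame == "child":
        ang = eng.body_angle(joint_child, q)
        ca, sa = np.cos(ang), np.sin(ang)
        F = np.stack([ca * F[0] + sa * F[1], -sa * F[0] + ca * F[1]])
    if state.q.ndim == 1:
        return F[:, 0]
    return F


def path_kinematics(model: ModelSpec, q, u, muscle=None):
    """Path length, lengthening speed, and per-coordinate moment arms.

    Moment arm of coordinate j is ``-d l_MT / d q_j``; the path velocity is
    the chain-rule sum over generalized speeds.  If ``muscle`` is None all
    muscles are returned.
    """
    eng = _engine_for(model)
    q2 = np.asarray(q, dtype=float).reshape(model.nq, -1)
    u2 = np.asarray(u, dtype=float).reshape(model.nq, -1)
    L, V, arms = eng.muscle_geometry(q2, u2)
    if muscle is not None:
        i = eng.muscle_names.index(muscle)
        if np.asarray(q).ndim == 1:
            return L[i, 0], V[i, 0], arms[0, i]
        return L[i], V[i], arms[:, i]
    return L, V, arms


def total_energy(model: ModelSpec, q, u):
    """Kinetic plus gravitational potential energy (springs excluded)."""
    eng = _engine_for(model)
    q2 = np.asarray(q, dtype=float).reshape(model.nq, -1)
    u2 = np.asarray(u, dtype=float).reshape(model.nq, -1)
    e = eng.energy(q2, u2)
    return e[0] if np.asarray(q).ndim == 1 else e
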