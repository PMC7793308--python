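"""Smooth Hill-type muscle model.

A damped, continuously differentiable muscle consisting of four normalized
characteristic curves (active force--length, passive force--length,
force--velocity, tendon force--length), first-order activation dynamics with
asymmetric time constants, and either a rigid tendon (fiber kinematics follow
directly from musculotendon length) or a compliant tendon whose normalized
force is carried as a state variable and pinned by an implicit
fiber--tendon equilibrium residual.

Everything here is elementwise and accepts scalars or numpy arrays; the
collocation layer relies on that for vectorized evaluation over a time grid.
All lengths are normalized by optimal fiber length, velocities by the maximum
shortening velocity, and forces by maximum isometric force unless a docstring
says otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "MuscleParams",
    "activation_derivative",
    "active_force_length",
    "passive_force_length",
    "force_velocity",
    "tendon_force_length",
    "inverse_tendon_force_length",
    "curves",
    "rigid_tendon_kinematics",
    "tendon_equilibrium_residual",
    "equilibrium_tendon_force",
    "tendon_force",
]


@dataclass
class MuscleParams:
    """Constants of one musculotendon actuator.

    Parameters
    ----------
    F_iso : float
        Maximum isometric fiber force, N.
    l_M_opt : float
        Optimal fiber length, m.
    l_T_slack : float
        Tendon slack length, m.
    v_max : float
        Maximum shortening velocity in optimal fiber lengths per second.
    alpha_opt : float
        Pennation angle at optimal fiber length, rad.  A constant-thickness
        pennation model is used: the fiber-height ``l_M_opt*sin(alpha_opt)``
        is invariant.
    beta : float
        Dimensionless fiber damping coefficient.
    tau_act, tau_deact : float
        Activation and deactivation time constants, s.
    rigid_tendon : bool
        If True the tendon is inextensible and fiber kinematics are purely
        geometric; otherwise normalized tendon force becomes a state.
    """

    name: str = "muscle"
    F_iso: float = 100.0
    l_M_opt: float = 0.10
    l_T_slack: float = 0.05
    v_max: float = 10.0
    alpha_opt: float = 0.0
    beta: float = 0.1
    tau_act: float = 0.015
    tau_deact: float = 0.060
    rigid_tendon: bool = True
    # characteristic-curve constants
    gamma_fl: float = 0.45
    k_pe: float = 4.0
    eps0: float = 0.6
    fv_d: tuple = (-0.318, -8.149, -0.374, 0.886)
    c1: float = 0.200
    c2: float = 0.995
    c3: float = 0.250
    k_T: float = 35.0

    def __post_init__(self):
        if self.F_iso <= 0:
            raise ValueError(f"{self.name}: F_iso must be > 0")
        if self.l_M_opt <= 0:
            raise ValueError(f"{self.name}: l_M_opt must be > 0")
        if self.l_T_slack < 0:
            raise ValueError(f"{self.name}: l_T_slack must be >= 0")
        if not (0.0 <= self.alpha_opt < np.pi / 2):
            raise ValueError(f"{self.name}: alpha_opt must lie in [0, pi/2)")
        if self.tau_act >= self.tau_deact:
            raise ValueError(f"{self.name}: tau_act must be < tau_deact")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fv_d"] = list(self.fv_d)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MuscleParams":
        d = dict(d)
        if "fv_d" in d:
            d["fv_d"] = tuple(d["fv_d"])
        return cls(**d)


# -- activation dynamics ------------------------------------------------------

_SMOOTH_B = 0.1


def activation_derivative(e, a, params: MuscleParams | None = None,
                          tau_act: float | None = None,
                          tau_deact: float | None = None):
    """Rate of change of activation, 1/s.

    Smooth blend between the activation branch (time constant scaled by
    ``0.5 + 1.5 a``) and the deactivation branch, so the derivative is C^1 in
    both excitation and activation.  ``e == a`` is a fixed point.
    """
    if params is not None:
        tau_act, tau_deact = params.tau_act, params.tau_deact
    if tau_act is None:
        tau_act, tau_deact = 0.015, 0.060
    e = np.asarray(e, dtype=float)
    a = np.asarray(a, dtype=float)
    f = 0.5 * np.tanh(_SMOOTH_B * (e - a))
    scale = 0.5 + 1.5 * a
    rate = (f + 0.5) / (tau_act * scale) + (0.5 - f) * scale / tau_deact
    return rate * (e - a)


# -- characteristic curves ----------------------------------------------------

def active_force_length(lm_tilde, gamma_fl: float = 0.45):
    """Gaussian active force--length curve; equals 1 at optimal length."""
    lm = np.asarray(lm_tilde, dtype=float)
    return np.exp(-((lm - 1.0) ** 2) / gamma_fl)


def passive_force_length(lm_tilde, k_pe: float = 4.0, eps0: float = 0.6):
    """Exponential passive force--length curve; 0 at optimal, 1 at 1+eps0."""
    lm = np.asarray(lm_tilde, dtype=float)
    return (np.exp(k_pe * (lm - 1.0) / eps0) - 1.0) / (np.exp(k_pe) - 1.0)


def force_velocity(vm_tilde, d=(-0.318, -8.149, -0.374, 0.886)):
    """Logarithmic force--velocity curve.

    ``vm_tilde`` is fiber velocity normalized by the maximum shortening
    velocity (negative = shortening).  Monotone increasing; ~0 at -1,
    ~1.002 at 0, >1 when lengthening.
    """
    d1, d2, d3, d4 = d
    v = np.asarray(vm_tilde, dtype=float)
    arg = d2 * v + d3
    return d1 * np.log(arg + np.sqrt(arg * arg + 1.0)) + d4


def _softplus(x, sharpness: float):
    # overflow-safe softplus(s*x)/s
    z = sharpness * np.asarray(x, dtype=float)
    return (np.logaddexp(0.0, z)) / sharpness


def tendon_force_length(lt_tilde, params: MuscleParams | None = None,
                        clamp: bool = True):
    """Exponential tendon force--length curve.

    The raw exponential is slightly negative at ``lt_tilde = 1`` (about
    -0.012 with the default constants); with ``clamp=True`` a softplus floor
    (sharpness 100) keeps the returned force smoothly nonnegative.  The raw
    curve (``clamp=False``) is what the analytic inverse round-trips.
    """
    p = params or MuscleParams()
    lt = np.asarray(lt_tilde, dtype=float)
    raw = p.c1 * np.exp(p.k_T * (lt - p.c2)) - p.c3
    if not clamp:
        return raw
    return _softplus(raw, 100.0)


def inverse_tendon_force_length(ft_tilde, params: MuscleParams | None = None):
    """Tendon length at which the raw tendon curve produces ``ft_tilde``.

    Requires ``ft_tilde > -c3``; violations raise with the muscle name.
    """
    p = params or MuscleParams()
    ft = np.asarray(ft_tilde, dtype=float)
    if np.any(ft <= -p.c3):
        raise ValueError(
            f"{p.name}: normalized tendon force must exceed -c3 = {-p.c3} "
            "for the tendon curve to be invertible")
    return p.c2 + np.log((ft + p.c3) / p.c1) / p.k_T


def curves(lm_tilde, vm_tilde, lt_tilde, params: MuscleParams | None = None):
    """Evaluate all four normalized curves: (f_act, f_pass, f_v, f_T).

    ``f_T`` is the raw (unclamped) tendon curve; force evaluation applies the
    softplus floor separately.
    """
    p = params or MuscleParams()
    return (active_force_length(lm_tilde, p.gamma_fl),
            passive_force_length(lm_tilde, p.k_pe, p.eps0),
            force_velocity(vm_tilde, p.fv_d),
            tendon_force_length(lt_tilde, p, clamp=False))


# -- fiber kinematics ---------------------------------------------------------

def rigid_tendon_kinematics(l_MT, v_MT, params: MuscleParams,
                            validate: bool = True):
    """Fiber state implied by path length for an inextensible tendon.

    Returns ``(lm_tilde, vm_tilde, cos_alpha)``.  With constant-thickness
    pennation the fiber height ``h = l_M_opt*sin(alpha_opt)`` is invariant,
    so ``l_M = sqrt((l_MT - l_T_slack)^2 + h^2)``.  Fiber velocity is the
    projection of the path velocity onto the fiber:
    ``v_M = v_MT * cos(alpha)``, normalized by ``v_max * l_M_opt``.
    """
    p = params
    l_MT = np.asarray(l_MT, dtype=float)
    v_MT = np.asarray(v_MT, dtype=float)
    w = l_MT - p.l_T_slack
    h = p.l_M_opt * np.sin(p.alpha_opt)
    l_M = np.sqrt(w * w + h * h)
    if validate and np.any(w <= 0) and h == 0.0:
        bad = np.atleast_1d(l_MT)[np.atleast_1d(w <= 0)]
        raise ValueError(
            f"{p.name}: non-physical geometry, path length {bad[:3]} "
            f"does not exceed tendon slack length {p.l_T_slack}")
    cos_alpha = w / l_M
    vm_tilde = v_MT * cos_alpha / (p.v_max * p.l_M_opt)
    return l_M / p.l_M_opt, vm_tilde, cos_alpha


# -- fiber--tendon equilibrium (compliant tendon) -----------------------------

def _compliant_fiber_state(l_MT, v_MT, ft_tilde, dft_dt, p: MuscleParams):
    lt_tilde = inverse_tendon_force_length(ft_tilde, p)
    l_T = lt_tilde * p.l_T_slack
    w = np.asarray(l_MT, dtype=float) - l_T
    h = p.l_M_opt * np.sin(p.alpha_opt)
    l_M = np.sqrt(w * w + h * h)
    cos_alpha = w / l_M
    # tendon lengthening rate from the force-rate state, by the chain rule
    # through the raw tendon curve: d lt/d ft = 1/(k_T (ft + c3)).
    v_T = p.l_T_slack * np.asarray(dft_dt, dtype=float) / (
        p.k_T * (np.asarray(ft_tilde, dtype=float) + p.c3))
    v_M = (v_MT - v_T) * cos_alpha
    vm_tilde = v_M / (p.v_max * p.l_M_opt)
    return l_M / p.l_M_opt, vm_tilde, cos_alpha


def tendon_equilibrium_residual(a, l_MT, v_MT, ft_tilde, dft_dt,
                                params: MuscleParams):
    """Normalized fiber--tendon force balance residual.

    Zero iff the tendon force state is consistent with the fiber force
    produced at activation ``a`` and the fiber kinematics implied by
    inverting the tendon curve.  With fiber damping ``beta > 0`` the residual
    is strictly monotone in ``ft_tilde`` near equilibrium, so the root is
    unique.
    """
    p = params
    lm, vm, cos_alpha = _compliant_fiber_state(l_MT, v_MT, ft_tilde, dft_dt, p)
    fiber = (np.asarray(a, dtype=float) * active_force_length(lm, p.gamma_fl)
             * force_velocity(vm, p.fv_d)
             + passive_force_length(lm, p.k_pe, p.eps0)
             + p.beta * vm)
    return np.asarray(ft_tilde, dtype=float) - cos_alpha * fiber


def equilibrium_tendon_force(a, l_MT, v_MT, params: MuscleParams,
                             dft_dt=0.0, lo: float = -0.2, hi: float = 5.0,
                             xtol: float = 1e-12) -> float:
    """Solve the equilibrium residual for the normalized tendon force.

    Scalar bisection/Brent root-find; used by tests and to initialize the
    compliant-tendon state, never inside the collocation residuals.
    """
    from scipy.optimize import brentq

    def res(ft):
        return float(tendon_equilibrium_residual(a, l_MT, v_MT, ft, dft_dt,
                                                 params))

    rlo, rhi = res(lo), res(hi)
    if rlo * rhi > 0:
        raise ValueError(f"{params.name}: no equilibrium bracket in "
                         f"[{lo}, {hi}] (residuals {rlo:.3g}, {rhi:.3g})")
    return brentq(res, lo, hi, xtol=xtol)


def tendon_force(a, l_MT, v_MT, params: MuscleParams, ft_tilde=None,
                 validate: bool = True):
    """Force carried along the musculotendon path, N.

    Rigid tendon: ``F_iso * cos(alpha) * (a f_act f_v + f_pass + beta vm)``.
    Compliant tendon: ``F_iso * ft_tilde`` (the state is the force).
    """
    p = params
    if not p.rigid_tendon:
        if ft_tilde is None:
            raise ValueError(f"{p.name}: compliant tendon needs ft_tilde")
        return p.F_iso * np.asarray(ft_tilde, dtype=float)
    lm, vm, cos_alpha = rigid_tendon_kinematics(l_MT, v_MT, p,
                                                validate=validate)
    fiber = (np.asarray(a, dtype=float) * active_force_length(lm, p.gamma_fl)
             * force_velocity(vm, p.fv_d)
             + passive_force_length(lm, p.k_pe, p.eps0) + p.beta * vm)
    return p.F_iso * cos_alpha * fiber
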