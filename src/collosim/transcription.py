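"""Direct-collocation transcription of continuous optimal-control problems.

Converts a problem (dynamics + goals + constraints, see
:mod:`collosim.problem`) into a finite nonlinear program using either the
second-order trapezoidal scheme or the third-order Hermite--Simpson scheme,
with multibody dynamics in explicit ("forward dynamics") or implicit
("inverse dynamics", accelerations as extra controls) form, and holonomic
constraints handled with Lagrange multipliers as controls plus, for
Hermite--Simpson, bounded velocity-correction variables at interval
midpoints.

Decision-vector layout (documented; indices via :class:`NLPStructure`):

    [ duration (1 slot, only if final time is free) |
      states, time-major: x_0, x_1, ..., x_{T-1}   (T x nx) |
      per-point control block: physical controls, lambda, accelerations w
      (implicit mode only)                          (T x nc) |
      midpoint velocity corrections gamma           (N x n_kin, HS only) |
      free model parameters                         (npar) ]

Time is normalized: states and controls live on tau in [0, 1] and the mesh
spacing is ``h = duration / N``.  A problem with N mesh intervals has N+1
(trapezoidal) or 2N+1 (Hermite--Simpson) time points.

The nonlinear program is solved with scipy's ``trust-constr`` interior-point
method.  Constraint Jacobians are central finite differences compressed
through the transcription's banded sparsity pattern (only variables adjacent
in time appear in any defect row); objective gradients are analytic per goal.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sps
from scipy.optimize import Bounds, NonlinearConstraint, minimize, BFGS

__all__ = ["TranscriptionConfig", "NLPStructure", "RawSolution",
           "build_grid", "trapezoidal_defect", "hermite_simpson_defect",
           "assemble_nlp", "solve_nlp", "check_gradient"]


@dataclass
class TranscriptionConfig:
    scheme: str = "hermite-simpson"          # 'hermite-simpson'|'trapezoidal'
    num_mesh_intervals: int = 25
    dynamics_mode: str = "explicit"          # 'explicit' | 'implicit'
    convergence_tol: float = 1e-3
    constraint_tol: float = 1e-3
    fd_step: float = 1e-6
    multiplier_bound: float = 1000.0
    velocity_correction_bound: float = 0.1
    acceleration_bound: float = 1000.0       # bound on implicit-mode w
    max_iterations: int = 3000
    # initial interior-point barrier when a guess is supplied; keeping it
    # small preserves warm starts that ride variable bounds
    warm_start_barrier: float = 1e-6
    # optional active-set (SLSQP) polish after the interior-point stage;
    # inexpensive on desk-scale programs and sharpens solutions whose
    # variables ride bounds, where barrier methods leave an offset
    polish: bool = False
    polish_iterations: int = 60

    def __post_init__(self):
        if self.scheme not in ("hermite-simpson", "trapezoidal"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.dynamics_mode not in ("explicit", "implicit"):
            raise ValueError(f"unknown dynamics mode {self.dynamics_mode!r}")
        if self.num_mesh_intervals < 2:
            raise ValueError("num_mesh_intervals must be >= 2")
        if min(self.convergence_tol, self.constraint_tol, self.fd_step) <= 0:
            raise ValueError("tolerances must be > 0")

    @property
    def n_points(self):
        N = self.num_mesh_intervals
        return 2 * N + 1 if self.scheme == "hermite-simpson" else N + 1


def build_grid(config: TranscriptionConfig, t0: float, tf: float):
    """Uniform time grid; Hermite--Simpson adds interval midpoints, so a
    problem with N mesh intervals has 2N+1 time points."""
    if tf <= t0:
        raise ValueError(f"tf ({tf}) must exceed t0 ({t0})")
    return np.linspace(t0, tf, config.n_points)


def trapezoidal_defect(x_k, x_k1, f_k, f_k1, h):
    """x_{k+1} - x_k - (h/2)(f_k + f_{k+1}); exact for linear integrands."""
    if np.any(np.asarray(h) <= 0):
        raise ValueError("mesh spacing h must be > 0")
    return np.asarray(x_k1) - np.asarray(x_k) \
        - (h / 2.0) * (np.asarray(f_k) + np.asarray(f_k1))


def hermite_simpson_defect(x_k, x_mid, x_k1, f_k, f_mid, f_k1, h):
    """Hermite interpolation defect and Simpson integration defect; both
    vanish identically on cubic trajectories with consistent derivatives."""
    if np.any(np.asarray(h) <= 0):
        raise ValueError("mesh spacing h must be > 0")
    x_k, x_mid, x_k1 = map(np.asarray, (x_k, x_mid, x_k1))
    f_k, f_mid, f_k1 = map(np.asarray, (f_k, f_mid, f_k1))
    interp = x_mid - 0.5 * (x_k + x_k1) - (h / 8.0) * (f_k - f_k1)
    integ = x_k1 - x_k - (h / 6.0) * (f_k + 4.0 * f_mid + f_k1)
    return interp, integ


def _quadrature_weights(config: TranscriptionConfig):
    """Normalized-time quadrature weights consistent with the scheme
    (sum to 1)."""
    N = config.num_mesh_intervals
    if config.scheme == "trapezoidal":
        w = np.full(N + 1, 1.0 / N)
        w[0] = w[-1] = 0.5 / N
    else:
        w = np.zeros(2 * N + 1)
        w[0::2] += 1.0 / (6 * N)
        w[2::2] += 1.0 / (6 * N)
        w[1::2] = 4.0 / (6 * N)
    return w


class NLPStructure:
    """Finite nonlinear program for one (problem, transcription) pair.

    Exposes the decision-vector layout, variable bounds, vectorized
    objective/gradient and constraint callables, the constraint lb/ub, and
    the banded Jacobian sparsity pattern used for finite-difference
    compression.
    """

    def __init__(self, problem, config: TranscriptionConfig):
        problem.validate()
        self.problem = problem
        self.config = config
        sys = problem.system
        self.system = sys
        self.hs = config.scheme == "hermite-simpson"
        self.implicit = config.dynamics_mode == "implicit"
        N = config.num_mesh_intervals
        self.N = N
        self.T = config.n_points
        self.nx = len(sys.state_names)
        self.ncu = len(sys.control_names)
        self.nlam = sys.n_kin
        self.nw = sys.n_speeds if self.implicit else 0
        self.nc = self.ncu + self.nlam + self.nw
        self.ngam = N * self.nlam if self.hs else 0
        self.npar = len(problem.parameters)
        lo, hi = problem.duration_bounds
        if not (np.isfinite(lo) and np.isfinite(hi)):
            raise ValueError("free final time requires finite duration "
                             "bounds")
        if lo > hi:
            raise ValueError("duration bounds out of order")
        if hi <= 0:
            raise ValueError("duration must be positive")
        self.free_time = lo < hi
        self.duration_fixed = lo if not self.free_time else None

        self.off_s = 1 if self.free_time else 0
        self.off_c = self.off_s + self.T * self.nx
        self.off_g = self.off_c + self.T * self.nc
        self.off_p = self.off_g + self.ngam
        self.n_vars = self.off_p + self.npar
        self.tau = np.linspace(0.0, 1.0, self.T)
        self.quad_w = _quadrature_weights(config)
        self.mesh_idx = np.arange(0, self.T, 2) if self.hs \
            else np.arange(self.T)
        self.mid_idx = np.arange(1, self.T, 2) if self.hs else np.empty(0, int)

        self._build_bounds()
        self._build_constraint_meta()
        self._build_sparsity()

    # ---- layout helpers

    def unpack(self, z):
        dt = z[0] if self.free_time else self.duration_fixed
        X = z[self.off_s:self.off_c].reshape(self.T, self.nx)
        C = z[self.off_c:self.off_g].reshape(self.T, self.nc)
        GAM = z[self.off_g:self.off_p].reshape(-1, self.nlam) \
            if self.ngam else np.zeros((0, self.nlam))
        P = z[self.off_p:]
        return dt, X, C, GAM, P

    def pack(self, dt, X, C, GAM=None, P=None):
        parts = []
        if self.free_time:
            parts.append([dt])
        parts.append(np.asarray(X, dtype=float).ravel())
        parts.append(np.asarray(C, dtype=float).ravel())
        if self.ngam:
            g = np.zeros((self.N, self.nlam)) if GAM is None else GAM
            parts.append(np.asarray(g, dtype=float).ravel())
        if self.npar:
            p = np.array([0.5 * (lo + hi) for lo, hi in
                          (pp.bounds for pp in self.problem.parameters)]) \
                if P is None else np.asarray(P, dtype=float)
            parts.append(p)
        return np.concatenate([np.atleast_1d(np.asarray(p, dtype=float))
                               for p in parts])

    def times(self, z):
        dt, *_ = self.unpack(z)
        return self.problem.t0 + self.tau * dt

    # ---- bounds and guess

    def _build_bounds(self):
        prob, sys = self.problem, self.system
        sb = prob.resolved_state_bounds()      # (nx, 2)
        cb = prob.resolved_control_bounds()    # (ncu, 2)
        if np.any(sb[:, 0] > sb[:, 1]) or np.any(cb[:, 0] > cb[:, 1]):
            raise ValueError("variable bounds have lower > upper")
        lb = np.empty(self.n_vars)
        ub = np.empty(self.n_vars)
        if self.free_time:
            lb[0], ub[0] = prob.duration_bounds
        lb[self.off_s:self.off_c] = np.tile(sb[:, 0], self.T)
        ub[self.off_s:self.off_c] = np.tile(sb[:, 1], self.T)
        # initial/final state pins tighten the endpoint-variable bounds
        for which, tp in (("initial", 0), ("final", self.T - 1)):
            for i, plo, phi in prob.endpoint_bounds(which):
                lb[self.off_s + tp * self.nx + i] = plo
                ub[self.off_s + tp * self.nx + i] = phi
        cfull_lo = np.concatenate([
            cb[:, 0],
            np.full(self.nlam, -self.config.multiplier_bound),
            np.full(self.nw, -self.config.acceleration_bound)])
        cfull_hi = np.concatenate([
            cb[:, 1],
            np.full(self.nlam, self.config.multiplier_bound),
            np.full(self.nw, self.config.acceleration_bound)])
        lb[self.off_c:self.off_g] = np.tile(cfull_lo, self.T)
        ub[self.off_c:self.off_g] = np.tile(cfull_hi, self.T)
        if self.ngam:
            lb[self.off_g:self.off_p] = -self.config.velocity_correction_bound
            ub[self.off_g:self.off_p] = self.config.velocity_correction_bound
        for r, par in enumerate(self.problem.parameters):
            plo, phi = par.bounds
            if plo > phi:
                raise ValueError(f"parameter {par.path!r}: bounds out of "
                                 "order")
            lb[self.off_p + r], ub[self.off_p + r] = plo, phi
        self.lb, self.ub = lb, ub

    def default_guess(self):
        """Midpoint of the variable bounds (0 where a side is unbounded)."""
        lo, hi = self.lb, self.ub
        mid = np.zeros(self.n_vars)
        m = np.isfinite(lo) & np.isfinite(hi)
        mid[m] = 0.5 * (lo[m] + hi[m])
        return np.clip(mid, lo, hi)

    # ---- constraints

    def _build_constraint_meta(self):
        nx, T, N = self.nx, self.T, self.N
        n_def = N * (2 * nx if self.hs else nx)
        n_kinrows = 2 * self.nlam * len(self.mesh_idx)
        self.n_path_sys = len(self.system.path_names)
        n_patheq = (self.n_path_sys + self.nw) * T
        self.custom_paths = list(self.problem.path_specs)
        n_custom = sum(pc.n_rows for pc in self.custom_paths) * T
        self.boundary_specs = list(self.problem.boundary_specs)
        for b in self.boundary_specs:
            b.bind(self.system)
        n_bound = sum(b.n_rows for b in self.boundary_specs)
        # Hermite-Simpson midpoint multipliers are tied to the mesh-point
        # average: lambda is piecewise-linear over the full interval.  With
        # free midpoint values the multipliers can oscillate point-to-point
        # (only their Simpson averages are pinned by the defects), which
        # leaves the pointwise accelerations non-physical.
        n_lamlin = N * self.nlam if self.hs else 0
        self.slices = {}
        o = 0
        self.slices["defects"] = slice(o, o + n_def); o += n_def
        self.slices["kinematic"] = slice(o, o + n_kinrows); o += n_kinrows
        self.slices["multiplier_linearity"] = slice(o, o + n_lamlin)
        o += n_lamlin
        self.slices["path"] = slice(o, o + n_patheq); o += n_patheq
        self.slices["custom_path"] = slice(o, o + n_custom); o += n_custom
        self.slices["boundary"] = slice(o, o + n_bound); o += n_bound
        self.n_cons = o
        clb = np.zeros(self.n_cons)
        cub = np.zeros(self.n_cons)
        # inequality bands for custom path constraints
        if n_custom:
            o = self.slices["custom_path"].start
            tgrid = self._fixed_time_grid()
            for pc in self.custom_paths:
                nr = pc.n_rows * T
                clb[o:o + nr] = np.asarray(pc.lower(tgrid)).ravel()
                cub[o:o + nr] = np.asarray(pc.upper(tgrid)).ravel()
                if np.any(clb[o:o + nr] > cub[o:o + nr]):
                    raise ValueError(
                        "path-constraint bounds cross (lower > upper)")
                o += nr
        self.c_lb, self.c_ub = clb, cub

    def _fixed_time_grid(self):
        if self.free_time:
            for pc in self.custom_paths:
                if pc.time_varying:
                    raise ValueError("time-varying path-constraint bounds "
                                     "require a fixed duration")
            return self.problem.t0 + self.tau
        return self.problem.t0 + self.tau * self.duration_fixed

    def _rates(self, X, C, t, P):
        x = X.T
        cu = C[:, :self.ncu].T
        lam = C[:, self.ncu:self.ncu + self.nlam].T
        if self.implicit:
            w = C[:, self.ncu + self.nlam:].T
            xdot = self.system.implicit_rate(x, cu, lam, w, t, P)
        else:
            xdot = self.system.rate(x, cu, lam, t, P)
        return np.ascontiguousarray(xdot)

    def constraints(self, z):
        dt, X, C, GAM, P = self.unpack(z)
        t = self.problem.t0 + self.tau * dt
        x = X.T
        cu = C[:, :self.ncu].T
        lam = C[:, self.ncu:self.ncu + self.nlam].T
        w = C[:, self.ncu + self.nlam:].T
        xdot = self._rates(X, C, t, P)
        if self.hs and self.nlam:
            xdot[:, self.mid_idx] += self.system.qdot_correction(
                x[:, self.mid_idx], GAM.T, P)
        F = xdot.T  # (T, nx)
        h = dt / self.N
        out = np.empty(self.n_cons)
        # defects
        if self.hs:
            a, m, b = F[0:-1:2], F[1::2], F[2::2]
            Xa, Xm, Xb = X[0:-1:2], X[1::2], X[2::2]
            interp = Xm - 0.5 * (Xa + Xb) - (h / 8.0) * (a - b)
            integ = Xb - Xa - (h / 6.0) * (a + 4.0 * m + b)
            d = np.concatenate([interp, integ], axis=1)  # (N, 2nx)
            out[self.slices["defects"]] = d.ravel()
        else:
            d = X[1:] - X[:-1] - (h / 2.0) * (F[1:] + F[:-1])
            out[self.slices["defects"]] = d.ravel()
        # kinematic constraints at mesh points
        if self.nlam:
            phi, Gu = self.system.kin_residuals(x[:, self.mesh_idx], P)
            out[self.slices["kinematic"]] = np.concatenate(
                [phi, Gu]).T.ravel()
        elif self.slices["kinematic"].stop > self.slices["kinematic"].start:
            out[self.slices["kinematic"]] = 0.0
        sl = self.slices["multiplier_linearity"]
        if sl.stop > sl.start:
            L = C[:, self.ncu:self.ncu + self.nlam]
            out[sl] = (L[1::2] - 0.5 * (L[0:-1:2] + L[2::2])).ravel()
        # equality path residuals
        o = self.slices["path"].start
        if self.n_path_sys:
            r = self.system.path_residuals(x, cu, lam, t, P)  # (npath, T)
            n = self.n_path_sys * self.T
            out[o:o + n] = r.T.ravel()
            o += n
        if self.nw:
            r = self.system.implicit_residual(x, cu, lam, w, t, P)
            n = self.nw * self.T
            out[o:o + n] = r.T.ravel()
            o += n
        # custom path constraints
        o = self.slices["custom_path"].start
        for pc in self.custom_paths:
            r = pc.residual(x, cu, t, P)
            n = pc.n_rows * self.T
            out[o:o + n] = np.asarray(r).T.ravel() if pc.n_rows > 1 \
                else np.asarray(r).ravel()
            o += n
        # boundary constraints
        o = self.slices["boundary"].start
        c0, cT = C[0, :self.ncu], C[-1, :self.ncu]
        for b in self.boundary_specs:
            r = np.atleast_1d(b.residual(X[0], X[-1], c0, cT, dt, P))
            out[o:o + b.n_rows] = r
            o += b.n_rows
        return out

    # ---- objective

    def objective_terms(self, z):
        """Per-goal objective values (same quadrature as the solver)."""
        dt, X, C, GAM, P = self.unpack(z)
        t = self.problem.t0 + self.tau * dt
        x, cu = X.T, C[:, :self.ncu].T
        vals = {}
        for goal in self.problem.goals:
            if goal.is_integral:
                g = goal.integrand(x, cu, t, P)[0]
                vals[goal.label] = dt * float(self.quad_w @ g)
            else:
                vals[goal.label] = float(goal.terminal(X[-1], dt, P)[0])
        return vals

    def objective(self, z):
        return float(sum(self.objective_terms(z).values()))

    def objective_grad(self, z):
        dt, X, C, GAM, P = self.unpack(z)
        t = self.problem.t0 + self.tau * dt
        x, cu = X.T, C[:, :self.ncu].T
        gX = np.zeros((self.T, self.nx))
        gC = np.zeros((self.T, self.nc))
        gdt = 0.0
        gP = np.zeros(self.npar)
        w = self.quad_w
        for goal in self.problem.goals:
            if goal.is_integral:
                g, dgx, dgc, dgt, dgp = goal.integrand(x, cu, t, P)
                gX += dt * (w[:, None] * dgx.T)
                gC[:, :self.ncu] += dt * (w[:, None] * dgc.T)
                gdt += float(w @ g)
                if dgt is not None:
                    gdt += dt * float(w @ (dgt * self.tau))
                if dgp is not None:
                    gP += dt * (dgp @ w)
            else:
                val, dxT, ddt, dgp = goal.terminal(X[-1], dt, P)
                gX[-1] += dxT
                gdt += ddt
                if dgp is not None:
                    gP += dgp
        grad = np.zeros(self.n_vars)
        if self.free_time:
            grad[0] = gdt
        grad[self.off_s:self.off_c] = gX.ravel()
        grad[self.off_c:self.off_g] = gC.ravel()
        grad[self.off_p:] = gP
        return grad

    def objective_hess(self, z):
        """Analytic Hessian of the objective.

        Integral goals contribute per-point diagonal state/control blocks
        plus duration cross terms from the product rule on
        ``dt * sum(w_t g_t)``; goals without curvature information (FD-based
        integrands) contribute zero, which only slows local convergence.
        """
        dt, X, C, GAM, P = self.unpack(z)
        t = self.problem.t0 + self.tau * dt
        x, cu = X.T, C[:, :self.ncu].T
        w = self.quad_w
        dxx = np.zeros((self.nx, self.T))
        dcc = np.zeros((self.ncu, self.T))
        cross_x = np.zeros((self.nx, self.T))   # d2/dx ddt
        cross_c = np.zeros((self.ncu, self.T))
        hdt = 0.0
        for goal in self.problem.goals:
            if not goal.is_integral:
                continue
            g, gx, gc, gt, _ = goal.integrand(x, cu, t, P)
            parts = goal.hessian(x, cu, t, P)
            if parts is not None:
                gxx, gcc, gxt, gct, gtt = parts
                dxx += dt * w * gxx
                dcc += dt * w * gcc
                cross_x += dt * w * self.tau * gxt
                cross_c += dt * w * self.tau * gct
                hdt += dt * float(w @ (gtt * self.tau ** 2))
            cross_x += w * gx
            cross_c += w * gc
            if gt is not None:
                hdt += 2.0 * float(w @ (gt * self.tau))
        rows, cols, vals = [], [], []

        def diag(block, off, width):
            idx = off + np.arange(self.T)[:, None] * width \
                + np.arange(block.shape[0])[None, :]
            idx = idx.ravel()
            v = block.T.ravel()
            rows.append(idx); cols.append(idx); vals.append(v)

        diag(dxx, self.off_s, self.nx)
        dcc_full = np.zeros((self.nc, self.T))
        dcc_full[:self.ncu] = dcc
        diag(dcc_full, self.off_c, self.nc)
        if self.free_time:
            cross_c_full = np.zeros((self.T, self.nc))
            cross_c_full[:, :self.ncu] = cross_c.T
            cx = np.concatenate([cross_x.T.ravel(), cross_c_full.ravel()])
            ci = np.concatenate([
                self.off_s + np.arange(self.T * self.nx),
                self.off_c + np.arange(self.T * self.nc)])
            rows.append(np.zeros_like(ci)); cols.append(ci); vals.append(cx)
            rows.append(ci); cols.append(np.zeros_like(ci)); vals.append(cx)
            rows.append(np.array([0])); cols.append(np.array([0]))
            vals.append(np.array([hdt]))
        return sps.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows),
                                    np.concatenate(cols))),
            shape=(self.n_vars, self.n_vars)).tocsr()

    # ---- sparsity

    def _cols_state(self, tp):
        return self.off_s + tp * self.nx + np.arange(self.nx)

    def _cols_ctrl(self, tp):
        return self.off_c + tp * self.nc + np.arange(self.nc)

    def _build_sparsity(self):
        rows, cols = [], []

        def add(r0, nrows, cset):
            cset = np.asarray(cset, dtype=int)
            for r in range(r0, r0 + nrows):
                rows.append(np.full(cset.size, r))
                cols.append(cset)

        par_cols = self.off_p + np.arange(self.npar)
        dt_col = [0] if self.free_time else []
        o = self.slices["defects"].start
        nxr = 2 * self.nx if self.hs else self.nx
        for k in range(self.N):
            pts = [2 * k, 2 * k + 1, 2 * k + 2] if self.hs else [k, k + 1]
            cset = np.concatenate(
                [self._cols_state(tp) for tp in pts]
                + [self._cols_ctrl(tp) for tp in pts]
                + ([self.off_g + k * self.nlam + np.arange(self.nlam)]
                   if self.ngam else [])
                + [par_cols, np.asarray(dt_col, dtype=int)])
            add(o + k * nxr, nxr, cset)
        o = self.slices["kinematic"].start
        for i, tp in enumerate(self.mesh_idx):
            if not self.nlam:
                break
            cset = np.concatenate([self._cols_state(tp), par_cols])
            add(o + i * 2 * self.nlam, 2 * self.nlam, cset)
        sl = self.slices["multiplier_linearity"]
        if sl.stop > sl.start:
            o = sl.start
            for k in range(self.N):
                cols_lam = [self.off_c + tp * self.nc + self.ncu
                            + np.arange(self.nlam)
                            for tp in (2 * k, 2 * k + 1, 2 * k + 2)]
                add(o + k * self.nlam, self.nlam, np.concatenate(cols_lam))
        o = self.slices["path"].start
        nper = self.n_path_sys + self.nw
        for tp in range(self.T if nper else 0):
            cset = np.concatenate([self._cols_state(tp),
                                   self._cols_ctrl(tp), par_cols])
            add(o + tp * nper, nper, cset)
        o = self.slices["custom_path"].start
        for pc in self.custom_paths:
            for tp in range(self.T):
                cset = pc.sparsity_cols(self, tp)
                add(o + tp * pc.n_rows, pc.n_rows, cset)
            o += pc.n_rows * self.T
        o = self.slices["boundary"].start
        for b in self.boundary_specs:
            cset = np.concatenate(
                [self._cols_state(0), self._cols_state(self.T - 1),
                 self._cols_ctrl(0), self._cols_ctrl(self.T - 1), par_cols,
                 np.asarray(dt_col, dtype=int)])
            add(o, b.n_rows, cset)
            o += b.n_rows
        if rows:
            r = np.concatenate(rows)
            c = np.concatenate(cols)
        else:
            r = c = np.zeros(0, dtype=int)
        self.jac_sparsity = sps.coo_matrix(
            (np.ones(r.size, dtype=np.int8), (r, c)),
            shape=(self.n_cons, self.n_vars)).tocsr()

    # ---- audit

    def audit(self, z):
        """Re-evaluate every constraint block outside the solver; returns
        max violation per block."""
        c = self.constraints(z)
        viol = np.maximum(c - self.c_ub, self.c_lb - c)
        out = {}
        for name, sl in self.slices.items():
            block = viol[sl]
            out[name] = float(np.max(block)) if block.size else 0.0
        out["max"] = float(np.max(viol)) if viol.size else 0.0
        return out


def assemble_nlp(problem, config: TranscriptionConfig) -> NLPStructure:
    """Transcribe ``problem`` under ``config``; see :class:`NLPStructure`."""
    return NLPStructure(problem, config)


@dataclass
class RawSolution:
    z: np.ndarray
    objective: float
    status: str                    # converged | max-iterations | infeasible
    iterations: int
    constraint_violation: float
    audit: dict
    objective_terms: dict
    message: str = ""


def solve_nlp(nlp: NLPStructure, guess=None, max_iterations=None,
              verbose: int = 0) -> RawSolution:
    """Solve the transcribed program with trust-constr.

    Convergence is declared on the interior-point method's own gtol test or
    on a scaled KKT test evaluated in a callback: the Lagrangian-gradient
    norm divided by the standard multiplier scaling
    ``s_d = max(s_max, ||v||_1 / n_mult) / s_max`` (s_max = 100) must fall
    below the convergence tolerance while the constraint violation is within
    the constraint tolerance.  The scaling keeps the test meaningful when
    the solver's internal penalty inflates the multipliers.

    Returns the best iterate even without convergence, flagged through
    ``status``.  A NaN anywhere in the guess is a validation error raised
    before the solver runs.
    """
    cfg = nlp.config
    z0 = nlp.default_guess() if guess is None else np.asarray(guess,
                                                              dtype=float)
    if z0.shape != (nlp.n_vars,):
        raise ValueError(f"guess has shape {z0.shape}, expected "
                         f"({nlp.n_vars},)")
    if not np.all(np.isfinite(z0)):
        raise ValueError("guess contains NaN or infinite entries")
    z0 = np.clip(z0, nlp.lb, nlp.ub)
    con = NonlinearConstraint(
        nlp.constraints, nlp.c_lb, nlp.c_ub, jac="3-point",
        finite_diff_jac_sparsity=nlp.jac_sparsity,
        finite_diff_rel_step=cfg.fd_step)
    maxiter = max_iterations or cfg.max_iterations

    # Warm restarts: the interior-point stage re-initializes its slack
    # variables away from the supplied point, which degrades an
    # already-feasible guess.  For such guesses on moderate-size programs an
    # active-set SQP step converges in a handful of iterations, so try it
    # first and keep the result if it certifies feasibility and does not
    # worsen the objective.
    all_equality = np.array_equal(nlp.c_lb, nlp.c_ub)
    if (guess is not None and all_equality and nlp.n_vars <= 800
            and nlp.audit(z0)["max"] <= 10 * cfg.constraint_tol):
        from scipy.optimize._numdiff import approx_derivative

        def _cjac(z):
            return approx_derivative(nlp.constraints, z, method="3-point",
                                     rel_step=cfg.fd_step,
                                     sparsity=nlp.jac_sparsity).toarray()

        res = minimize(nlp.objective, z0, jac=nlp.objective_grad,
                       method="SLSQP", bounds=list(zip(nlp.lb, nlp.ub)),
                       constraints=[dict(type="eq", fun=nlp.constraints,
                                         jac=_cjac)],
                       options=dict(maxiter=min(maxiter, 100),
                                    ftol=1e-12))
        audit = nlp.audit(res.x)
        f0 = nlp.objective(z0)
        # repairing residual infeasibility of the guess may raise the
        # objective slightly; reject only clearly worse points
        if res.success and audit["max"] <= cfg.constraint_tol \
                and res.fun <= f0 + 1e-3 * max(1.0, abs(f0)):
            return RawSolution(
                z=res.x, objective=float(res.fun), status="converged",
                iterations=int(res.nit),
                constraint_violation=float(audit["max"]), audit=audit,
                objective_terms=nlp.objective_terms(res.x),
                message=str(res.message))

    s_max = 100.0
    barrier_goal = 1e-3 * max(cfg.convergence_tol, 1e-8) ** 0.5
    f_hist = []
    stall_window = 30

    def scaled_kkt_reached(state):
        f_hist.append(state.fun)
        mu = getattr(state, "barrier_parameter", 0.0)
        if state.constr_violation > cfg.constraint_tol or mu > barrier_goal:
            return False
        v_abs = np.concatenate([np.abs(np.ravel(v)) for v in state.v]) \
            if state.v else np.zeros(1)
        s_d = max(s_max, v_abs.sum() / max(v_abs.size, 1)) / s_max
        scale = max(1.0, abs(state.fun))

        def span(w):
            # trailing objective variation; usable from the third iterate
            # so a restart at an already-optimal point can exit quickly
            if len(f_hist) < 3:
                return np.inf
            tail = f_hist[-min(w, len(f_hist)):]
            return max(tail) - min(tail)

        # scaled dual test alone can be permissive when multipliers are
        # large, so pair it with a short objective-stagnation check
        if (state.optimality / s_d <= cfg.convergence_tol
                and span(10) <= 10 * cfg.convergence_tol * scale):
            return True
        # acceptable-level stop: feasible, barrier converged, and the
        # objective stagnant over a longer trailing window (interior-point
        # optimality measures can stall when many variables ride bounds)
        return span(stall_window) <= 0.1 * stall_window \
            * cfg.convergence_tol * scale

    mu0 = 0.1 if guess is None else cfg.warm_start_barrier
    res = minimize(
        nlp.objective, z0, jac=nlp.objective_grad, hess=nlp.objective_hess,
        bounds=Bounds(nlp.lb, nlp.ub), constraints=[con],
        method="trust-constr",
        callback=lambda xk, state: scaled_kkt_reached(state),
        options=dict(gtol=cfg.convergence_tol, xtol=1e-12,
                     barrier_tol=cfg.convergence_tol, maxiter=maxiter,
                     initial_barrier_parameter=mu0, verbose=verbose))
    z_best, fun_best, niter = res.x, float(res.fun), int(res.niter)
    if cfg.polish:
        from scipy.optimize._numdiff import approx_derivative

        def cjac(z):
            return approx_derivative(nlp.constraints, z, method="3-point",
                                     rel_step=cfg.fd_step,
                                     sparsity=nlp.jac_sparsity).toarray()

        ineq = not np.array_equal(nlp.c_lb, nlp.c_ub)
        if not ineq:  # SLSQP polish implemented for all-equality programs
            res2 = minimize(
                nlp.objective, z_best, jac=nlp.objective_grad,
                method="SLSQP", bounds=list(zip(nlp.lb, nlp.ub)),
                constraints=[dict(type="eq", fun=nlp.constraints,
                                  jac=cjac)],
                options=dict(maxiter=cfg.polish_iterations, ftol=1e-12))
            aud2 = nlp.audit(res2.x)
            # feasibility repair may raise the objective slightly; adopt
            # the polished point unless it is clearly worse
            if aud2["max"] <= cfg.constraint_tol and \
                    res2.fun <= fun_best + 1e-3 * max(1.0, abs(fun_best)):
                z_best, fun_best = res2.x, float(res2.fun)
                niter += int(res2.nit)
    audit = nlp.audit(z_best)
    feasible = audit["max"] <= cfg.constraint_tol
    if res.status in (1, 2, 3) and feasible:
        status = "converged"
    elif res.status == 0:
        status = "converged" if cfg.polish and feasible \
            else "max-iterations"
    else:
        status = "infeasible"
    return RawSolution(
        z=z_best, objective=fun_best, status=status,
        iterations=niter,
        constraint_violation=float(max(audit["max"], 0.0)),
        audit=audit, objective_terms=nlp.objective_terms(z_best),
        message=str(res.message))


def check_gradient(nlp: NLPStructure, z, rel_tol: float = 1e-4):
    """Compare the analytic objective gradient against central finite
    differences; returns the worst relative mismatch."""
    from scipy.optimize._numdiff import approx_derivative
    g = nlp.objective_grad(z)
    g_fd = approx_derivative(nlp.objective, z, method="3-point",
                             rel_step=1e-7)
    scale = np.maximum(np.abs(g), np.maximum(np.abs(g_fd), 1e-8))
    return float(np.max(np.abs(g - g_fd) / scale))
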