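"""Time-gridded trajectories, solutions, and STO-style text I/O.

The on-disk dialect is the tab-separated column time-series familiar from
biomechanics tooling: a metadata header block (``key=value`` lines, first
line the trajectory name, terminated by ``endheader``), one row of column
names with ``time`` first, then one row per time point.  Values are written
with 17 significant digits so write -> read round-trips bit-identically.
Optional metadata keys ``states``, ``controls``, ``multipliers`` (comma
lists) and ``parameters`` (``path:value`` pairs separated by ``;``) preserve
column roles and model parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Trajectory", "Solution", "read_timeseries", "write_timeseries",
           "guess_from_trajectory", "solution_from_raw"]


class Trajectory:
    """Named columns over a strictly increasing time grid.

    Columns are classified as states, controls, or multipliers; unclassified
    columns are allowed (plain data).  All columns share the grid length.
    """

    def __init__(self, time, columns: dict, states=(), controls=(),
                 multipliers=(), parameters=None, name="trajectory"):
        self.time = np.asarray(time, dtype=float)
        if self.time.ndim != 1 or self.time.size < 2:
            raise ValueError("time grid needs >= 2 points")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        self.data = {}
        for nm, col in columns.items():
            col = np.asarray(col, dtype=float)
            if col.shape != self.time.shape:
                raise ValueError(f"column {nm!r} has length {col.size}, "
                                 f"grid has {self.time.size}")
            if nm in self.data:
                raise ValueError(f"duplicate column {nm!r}")
            self.data[nm] = col
        for role, names in (("states", states), ("controls", controls),
                            ("multipliers", multipliers)):
            missing = [nm for nm in names if nm not in self.data]
            if missing:
                raise ValueError(f"{role} name(s) {missing} not in columns")
        self.states = list(states)
        self.controls = list(controls)
        self.multipliers = list(multipliers)
        self.parameters = dict(parameters or {})
        self.name = name

    @property
    def columns(self):
        return list(self.data)

    @property
    def duration(self):
        return float(self.time[-1] - self.time[0])

    def __getitem__(self, name):
        return self.data[name]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.time, **self.data})

    def interpolant(self, names=None, kind="cubic"):
        """Callable t -> array (len(names), len(t)); cubic spline when the
        grid allows, linear otherwise."""
        from scipy.interpolate import CubicSpline, interp1d
        names = list(names if names is not None else self.columns)
        Y = np.stack([self.data[nm] for nm in names], axis=1)
        if kind == "cubic" and self.time.size >= 4:
            sp = CubicSpline(self.time, Y)
        else:
            sp = interp1d(self.time, Y, axis=0, kind="linear",
                          fill_value="extrapolate")
        return lambda t: np.atleast_2d(sp(np.asarray(t))).reshape(
            np.size(t), len(names)).T

    def resample(self, new_time):
        """Interpolate every column onto a new grid inside the current span;
        endpoint values are preserved exactly when the endpoints match."""
        new_time = np.asarray(new_time, dtype=float)
        f = self.interpolant()
        vals = f(new_time)
        cols = {nm: vals[i] for i, nm in enumerate(self.columns)}
        # exact endpoints
        for nm in self.columns:
            if np.isclose(new_time[0], self.time[0]):
                cols[nm][0] = self.data[nm][0]
            if np.isclose(new_time[-1], self.time[-1]):
                cols[nm][-1] = self.data[nm][-1]
        return Trajectory(new_time, cols, self.states, self.controls,
                          self.multipliers, self.parameters, self.name)


class Solution(Trajectory):
    """A trajectory plus solver outcome: success flag, objective value,
    iteration count, per-goal objective terms, and the post-solve
    constraint-residual audit."""

    def __init__(self, *args, success=False, status="unknown",
                 objective=np.nan, iterations=0, objective_terms=None,
                 residuals=None, **kw):
        super().__init__(*args, **kw)
        self.success = bool(success)
        self.status = status
        self.objective = float(objective)
        self.iterations = int(iterations)
        self.objective_terms = dict(objective_terms or {})
        self.residuals = dict(residuals or {})


# -- STO-style I/O ------------------------------------------------------------

def write_timeseries(traj: Trajectory, path):
    cols = traj.columns
    with open(path, "w") as fh:
        fh.write(f"{traj.name}\n")
        fh.write(f"nRows={traj.time.size}\n")
        fh.write(f"nColumns={len(cols) + 1}\n")
        for role in ("states", "controls", "multipliers"):
            names = getattr(traj, role)
            if names:
                fh.write(f"{role}={','.join(names)}\n")
        if traj.parameters:
            fh.write("parameters=" + ";".join(
                f"{k}:{v:.17g}" for k, v in traj.parameters.items()) + "\n")
        fh.write("endheader\n")
        fh.write("\t".join(["time"] + cols) + "\n")
        M = np.column_stack([traj.time] + [traj.data[c] for c in cols])
        for row in M:
            fh.write("\t".join(f"{v:.17g}" for v in row) + "\n")


def read_timeseries(path) -> Trajectory:
    meta = {}
    name = None
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    for i, line in enumerate(lines):
        s = line.strip()
        if s == "endheader":
            break
        if "=" in s:
            k, _, v = s.partition("=")
            meta[k.strip()] = v.strip()
        elif s and name is None:
            name = s
        elif s:
            raise ValueError(f"{path}: malformed header at line {i + 1}: "
                             f"{s!r}")
    else:
        raise ValueError(f"{path}: missing 'endheader' line")
    header_row = i + 1
    if header_row >= len(lines):
        raise ValueError(f"{path}: no column-name row after endheader")
    names = lines[header_row].rstrip("\n").split("\t")
    if names[0] != "time":
        raise ValueError(f"{path}: line {header_row + 1}: first column must "
                         f"be 'time', got {names[0]!r}")
    if len(set(names)) != len(names):
        raise ValueError(f"{path}: line {header_row + 1}: duplicate column "
                         "names")
    rows = []
    for ln, line in enumerate(lines[header_row + 1:], header_row + 2):
        s = line.strip()
        if not s:
            continue
        vals = s.split("\t")
        if len(vals) != len(names):
            raise ValueError(f"{path}: line {ln}: expected {len(names)} "
                             f"values, got {len(vals)}")
        try:
            rows.append([float(v) for v in vals])
        except ValueError:
            raise ValueError(f"{path}: line {ln}: non-numeric value")
    M = np.asarray(rows)
    if M.shape[0] < 2:
        raise ValueError(f"{path}: need at least two data rows")
    time = M[:, 0]
    if np.any(np.diff(time) <= 0):
        bad = int(np.argmax(np.diff(time) <= 0))
        raise ValueError(f"{path}: line {header_row + 3 + bad}: time is not "
                         "strictly increasing")
    cols = {nm: M[:, j + 1] for j, nm in enumerate(names[1:])}

    def split(key):
        return [s for s in meta.get(key, "").split(",") if s]

    params = {}
    for item in meta.get("parameters", "").split(";"):
        if item:
            k, _, v = item.partition(":")
            params[k] = float(v)
    return Trajectory(time, cols, split("states"), split("controls"),
                      split("multipliers"), params, name or "trajectory")


# -- NLP interop --------------------------------------------------------------

def solution_from_raw(nlp, raw) -> Solution:
    """Assemble a :class:`Solution` from a solved NLP decision vector."""
    sys = nlp.system
    dt, X, C, GAM, P = nlp.unpack(raw.z)
    # a failed solve can return an iterate with a non-physical duration;
    # clip only for grid construction so the trajectory stays inspectable
    lo, hi = nlp.problem.duration_bounds
    dt = float(np.clip(dt, max(lo, 1e-9), hi))
    time = nlp.problem.t0 + nlp.tau * dt
    cols = {}
    for i, nm in enumerate(sys.state_names):
        cols[nm] = X[:, i]
    for j, nm in enumerate(sys.control_names):
        cols[nm] = C[:, j]
    mult_names = []
    for k in range(nlp.nlam):
        nm = f"lambda_{k}"
        cols[nm] = C[:, nlp.ncu + k]
        mult_names.append(nm)
    params = {par.path: float(P[r])
              for r, par in enumerate(nlp.problem.parameters)}
    gamma = np.asarray(GAM) if nlp.ngam else None
    gamma_times = time[1::2] if nlp.ngam else None
    sol = Solution(
        time, cols, states=list(sys.state_names),
        controls=list(sys.control_names), multipliers=mult_names,
        parameters=params, name="solution",
        success=(raw.status == "converged"), status=raw.status,
        objective=raw.objective, iterations=raw.iterations,
        objective_terms=raw.objective_terms, residuals=raw.audit)
    # midpoint velocity-correction variables ride along for guess chaining
    sol.gamma = gamma
    sol.gamma_times = gamma_times
    return sol


def guess_from_trajectory(nlp, traj: Trajectory):
    """Map a trajectory onto an NLP decision vector (guess chaining).

    Columns are matched by name; anything absent falls back to the
    midpoint-of-bounds default.  Multipliers map onto the lambda block;
    implicit-mode accelerations are seeded from the numerical derivative of
    the matching speed columns.
    """
    z = nlp.default_guess()
    dt = np.clip(traj.duration, *nlp.problem.duration_bounds) \
        if nlp.free_time else nlp.duration_fixed
    if nlp.free_time:
        z[0] = dt
    tgrid = nlp.problem.t0 + nlp.tau * dt
    span = (traj.time[0], traj.time[-1])
    ts = np.clip(tgrid, *span)
    f = traj.interpolant()
    vals = f(ts)
    idx = {nm: i for i, nm in enumerate(traj.columns)}
    X = z[nlp.off_s:nlp.off_c].reshape(nlp.T, nlp.nx)
    for i, nm in enumerate(nlp.system.state_names):
        if nm in idx:
            X[:, i] = vals[idx[nm]]
    C = z[nlp.off_c:nlp.off_g].reshape(nlp.T, nlp.nc)
    for j, nm in enumerate(nlp.system.control_names):
        if nm in idx:
            C[:, j] = vals[idx[nm]]
    for k in range(nlp.nlam):
        nm = f"lambda_{k}"
        if nm in idx:
            C[:, nlp.ncu + k] = vals[idx[nm]]
    if nlp.nw:
        # seed the acceleration variables from forward dynamics at the
        # guessed states/controls so the implicit path residual starts at
        # (numerically) zero
        try:
            xdot = nlp.system.rate(X.T, C[:, :nlp.ncu].T,
                                   C[:, nlp.ncu:nlp.ncu + nlp.nlam].T,
                                   tgrid, z[nlp.off_p:])
            nq = nlp.system.n_speeds
            C[:, nlp.ncu + nlp.nlam:] = xdot[nq:2 * nq].T
        except NotImplementedError:
            model = getattr(nlp.system, "model", None)
            if model is not None:
                for k, coord in enumerate(model.coordinate_names()):
                    nm = f"{coord}_u"
                    if nm in idx:
                        C[:, nlp.ncu + nlp.nlam + k] = np.gradient(
                            vals[idx[nm]], tgrid)
    if nlp.ngam and getattr(traj, "gamma", None) is not None:
        gsrc = np.asarray(traj.gamma)
        gts = np.asarray(traj.gamma_times)
        mid_t = tgrid[1::2]
        G = np.stack([np.interp(mid_t, gts, gsrc[:, k])
                      for k in range(gsrc.shape[1])], axis=1)
        z[nlp.off_g:nlp.off_p] = G.ravel()
    for r, par in enumerate(nlp.problem.parameters):
        if par.path in traj.parameters:
            z[nlp.off_p + r] = traj.parameters[par.path]
    z[nlp.off_s:nlp.off_c] = X.ravel()
    z[nlp.off_c:nlp.off_g] = C.ravel()
    return np.clip(z, nlp.lb, nlp.ub)
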