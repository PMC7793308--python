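"""Structured-text (YAML) serialization of models and study definitions.

A *model file* carries one :class:`~collosim.model.ModelSpec`; a *study
file* carries a model (inline or by path), a problem section (goals,
bounds, boundary/path constraints, parameters), and a solver section
(transcription settings plus an optional mesh-continuation ladder).  The
schema is one-to-one with the dataclasses; every default is written out
explicitly on save so files are self-describing.
"""

from __future__ import annotations

import dataclasses
import os

import numpy as np
import yaml

from . import model as md
from .muscle import MuscleParams
from .problem import (AverageSpeed, ControlEffortGoal, ControlEnvelope,
                      FinalTimeGoal, JointReactionGoal, Parameter,
                      PeriodicPair, ProblemDef, StateTrackingGoal,
                      register_parameter)
from .system import MuscularSystem
from .trajectory import read_timeseries
from .transcription import TranscriptionConfig

__all__ = ["model_to_dict", "model_from_dict", "save_model", "load_model",
           "load_study", "save_study"]


def _clean(x):
    if isinstance(x, (list, tuple)):
        return [_clean(v) for v in x]
    if isinstance(x, dict):
        return {k: _clean(v) for k, v in x.items()}
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, float) and x in (float("inf"), float("-inf")):
        return ".inf" if x > 0 else "-.inf"
    return x


def model_to_dict(spec: md.ModelSpec) -> dict:
    d = {
        "name": spec.name,
        "gravity": list(spec.gravity),
        "bodies": [dataclasses.asdict(b) for b in spec.bodies],
        "joints": [dataclasses.asdict(j) for j in spec.joints],
        "muscles": [{"params": m.params.to_dict(),
                     "path": [dataclasses.asdict(p) for p in m.path]}
                    for m in spec.muscles],
        "springs": [dataclasses.asdict(s) for s in spec.springs],
        "contacts": [dataclasses.asdict(c) for c in spec.contacts],
        "actuators": [dataclasses.asdict(a) for a in spec.actuators],
        "constraints": [],
    }
    for c in spec.constraints:
        item = dataclasses.asdict(c)
        item["kind"] = ("coupler" if isinstance(c, md.CoordinateCoupler)
                        else "point_coincidence")
        d["constraints"].append(item)
    return _clean(d)


def model_from_dict(d: dict) -> md.ModelSpec:
    def tup(x):
        return tuple(x) if isinstance(x, (list, tuple)) else x

    joints = []
    for j in d.get("joints", []):
        j = dict(j)
        j["coordinates"] = [
            md.Coordinate(c["name"], c.get("unit", "rad"),
                          tuple(c.get("bounds", (-np.inf, np.inf))))
            for c in j.get("coordinates", [])]
        for k in ("parent_point", "child_point", "axis"):
            if k in j:
                j[k] = tup(j[k])
        joints.append(md.Joint(**j))
    muscles = [md.Muscle(MuscleParams.from_dict(m["params"]),
                         [md.PathPoint(p["body"], tup(p["location"]))
                          for p in m["path"]])
               for m in d.get("muscles", [])]
    constraints = []
    for c in d.get("constraints", []):
        c = dict(c)
        kind = c.pop("kind")
        if kind == "coupler":
            constraints.append(md.CoordinateCoupler(**c))
        elif kind == "point_coincidence":
            c["point_a"] = tup(c["point_a"])
            c["point_b"] = tup(c["point_b"])
            constraints.append(md.PointCoincidence(**c))
        else:
            raise ValueError(f"unknown constraint kind {kind!r}")
    return md.ModelSpec(
        name=d.get("name", "model"),
        gravity=tuple(d.get("gravity", md.GRAVITY_DEFAULT)),
        bodies=[md.Body(b["name"], b["mass"], b.get("inertia", 0.0),
                        tup(b.get("com", (0.0, 0.0))))
                for b in d.get("bodies", [])],
        joints=joints, muscles=muscles,
        springs=[md.TorsionalSpring(**s) for s in d.get("springs", [])],
        contacts=[md.ContactElement(**{**c, "location": tup(c["location"])})
                  for c in d.get("contacts", [])],
        actuators=[md.CoordinateActuator(**a)
                   for a in d.get("actuators", [])],
        constraints=constraints)


def save_model(spec: md.ModelSpec, path):
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(spec), fh, sort_keys=False)


def load_model(path) -> md.ModelSpec:
    with open(path) as fh:
        return model_from_dict(yaml.safe_load(fh)).validate()


# -- study files --------------------------------------------------------------

_GOAL_KINDS = {"control_effort", "final_time", "state_tracking",
               "joint_reaction"}


def _goal_from_dict(g: dict, model, base_dir):
    g = dict(g)
    kind = g.pop("kind")
    if kind not in _GOAL_KINDS:
        raise ValueError(f"unknown goal kind {kind!r}")
    if kind == "control_effort":
        return ControlEffortGoal(**g)
    if kind == "final_time":
        return FinalTimeGoal(**g)
    if kind == "state_tracking":
        ref = g.pop("reference")
        if isinstance(ref, str):
            ref = read_timeseries(os.path.join(base_dir, ref))
        return StateTrackingGoal(ref, **g)
    return JointReactionGoal(model, g.pop("joint_child"), **g)


def load_study(path):
    """Read a study file; returns (ProblemDef, TranscriptionConfig,
    mesh_schedule)."""
    base_dir = os.path.dirname(os.path.abspath(path))
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    mdl = doc.get("model")
    if isinstance(mdl, str):
        spec = load_model(os.path.join(base_dir, mdl))
    else:
        spec = model_from_dict(mdl).validate()
    p = doc.get("problem", {})
    sys_ = MuscularSystem(spec)
    dur = p.get("duration", 1.0)
    prob = ProblemDef(
        system=sys_,
        duration=tuple(dur) if isinstance(dur, (list, tuple)) else float(dur),
        t0=float(p.get("t0", 0.0)),
        state_bounds={k: tuple(v) for k, v in
                      p.get("state_bounds", {}).items()},
        control_bounds={k: tuple(v) for k, v in
                        p.get("control_bounds", {}).items()},
        state_initial=dict(p.get("state_initial", {})),
        state_final=dict(p.get("state_final", {})),
        goals=[_goal_from_dict(g, spec, base_dir)
               for g in p.get("goals", [])])
    for b in p.get("boundary_constraints", []):
        b = dict(b)
        kind = b.pop("kind")
        if kind == "periodic":
            prob.boundary_constraints.append(PeriodicPair(**b))
        elif kind == "average_speed":
            prob.boundary_constraints.append(AverageSpeed(**b))
        else:
            raise ValueError(f"unknown boundary constraint kind {kind!r}")
    for pc in p.get("path_constraints", []):
        pc = dict(pc)
        kind = pc.pop("kind")
        if kind != "control_envelope":
            raise ValueError(f"unknown path constraint kind {kind!r}")
        prob.path_constraints.append(ControlEnvelope(**pc))
    for par in p.get("parameters", []):
        register_parameter(prob, par["path"], tuple(par["bounds"]))
    s = doc.get("solver", {})
    schedule = tuple(s.pop("mesh_continuation", ()))
    fields = {f.name for f in dataclasses.fields(TranscriptionConfig)}
    cfg = TranscriptionConfig(**{k: v for k, v in s.items() if k in fields})
    unknown = set(s) - fields
    if unknown:
        raise ValueError(f"unknown solver settings {sorted(unknown)}")
    return prob, cfg, schedule


def save_study(path, model_dict_or_spec, problem: dict, solver: dict):
    """Write a study file from plain dict sections (the inverse of
    :func:`load_study` for programmatically built studies)."""
    mdl = (model_to_dict(model_dict_or_spec)
           if isinstance(model_dict_or_spec, md.ModelSpec)
           else model_dict_or_spec)
    with open(path, "w") as fh:
        yaml.safe_dump(_clean({"model": mdl, "problem": problem,
                               "solver": solver}), fh, sort_keys=False)
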