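"""Reading and writing model definitions, gait data and profile tables.

Model definition files are JSON with top-level keys ``bodies``, ``joints``
and ``muscles``; all lengths in mm, all angles in degrees, axis vectors as
3-element arrays.  A JSON-schema description ships with the package at
``momentarms/data/model.schema.json``.  Gait samples travel as CSV with a
``t`` column (stride time in [0, 1)) and one ``<joint>_deg`` column per
joint; fitted trajectory coefficients as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import BodySegment, HingeJoint, KinematicChain
from .gait import GaitTrajectory, StridePhase
from .muscles import AttachmentPoint, MusclePath

__all__ = [
    "load_model", "save_model",
    "load_gait_csv", "save_gait_csv",
    "load_trajectories", "save_trajectories",
    "write_profile_csv", "write_sensitivity_csv",
]


def _require(mapping: dict, key: str, context: str):
    if key not in mapping:
        raise ValueError(f"model file: {context} is missing required key '{key}'")
    return mapping[key]


def load_model(path) -> tuple[KinematicChain, list[MusclePath]]:
    """Load a chain and its muscles from a JSON model definition."""
    with open(path) as fh:
        doc = json.load(fh)
    for key in ("bodies", "joints", "muscles"):
        if key not in doc or not isinstance(doc[key], list):
            raise ValueError(f"model file must contain a '{key}' list")

    bodies = []
    for entry in doc["bodies"]:
        bodies.append(BodySegment(
            name=_require(entry, "name", "body"),
            parent_joint=entry.get("parent_joint"),
            reference_length=entry.get("reference_length")))

    joints = []
    for entry in doc["joints"]:
        name = _require(entry, "name", "joint")
        joints.append(HingeJoint(
            name=name,
            parent_body=_require(entry, "parent_body", f"joint '{name}'"),
            child_body=_require(entry, "child_body", f"joint '{name}'"),
            center_local=_require(entry, "center", f"joint '{name}'"),
            axis_local=_require(entry, "axis", f"joint '{name}'"),
            angle_limits=tuple(entry.get("angle_limits", (-180.0, 180.0))),
            zero_pose_note=entry.get("zero_pose_note", "")))

    chain = KinematicChain(bodies, joints)

    muscles = []
    for entry in doc["muscles"]:
        name = _require(entry, "name", "muscle")
        attachments = []
        for i, att in enumerate(_require(entry, "attachments", f"muscle '{name}'")):
            body = _require(att, "body", f"muscle '{name}' attachment {i}")
            chain.body(body)  # raises on unknown body
            attachments.append(AttachmentPoint(
                body=body,
                local_position=_require(att, "xyz", f"muscle '{name}' attachment {i}"),
                label=att.get("label", "")))
        muscles.append(MusclePath(name=name, attachments=attachments,
                                  group=entry.get("group")))
    return chain, muscles


def save_model(path, chain: KinematicChain, muscles: list[MusclePath]) -> None:
    """Write a chain and muscles as a JSON model definition (sorted keys)."""
    doc = {
        "bodies": [
            {"name": b.name,
             **({"parent_joint": b.parent_joint} if b.parent_joint else {}),
             **({"reference_length": b.reference_length}
                if b.reference_length is not None else {})}
            for b in chain.bodies],
        "joints": [
            {"name": j.name, "parent_body": j.parent_body,
             "child_body": j.child_body,
             "center": [float(v) for v in j.center_local],
             "axis": [float(v) for v in j.axis_local],
             "angle_limits": list(j.angle_limits),
             "zero_pose_note": j.zero_pose_note}
            for j in chain.joints],
        "muscles": [
            {"name": m.name,
             **({"group": m.group} if m.group else {}),
             "attachments": [
                 {"body": a.body, "xyz": [float(v) for v in a.local_position],
                  "label": a.label}
                 for a in m.attachments]}
            for m in muscles],
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def load_gait_csv(path) -> dict[str, np.ndarray]:
    """Read gait samples: returns {'t': array, '<joint>': angle array (deg)}."""
    df = pd.read_csv(path)
    if "t" not in df.columns:
        raise ValueError("gait CSV must have a 't' column")
    out = {"t": df["t"].to_numpy(float)}
    if np.any((out["t"] < 0) | (out["t"] >= 1)):
        raise ValueError("gait CSV: t values must lie in [0, 1)")
    joint_cols = [c for c in df.columns if c.endswith("_deg")]
    if not joint_cols:
        raise ValueError("gait CSV needs at least one '<joint>_deg' column")
    for col in joint_cols:
        out[col[:-len("_deg")]] = df[col].to_numpy(float)
    return out


def save_gait_csv(path, t: np.ndarray,
                  angles: dict[str, np.ndarray]) -> None:
    df = pd.DataFrame({"t": t})
    for joint, vals in angles.items():
        df[f"{joint}_deg"] = vals
    df.to_csv(path, index=False)


def save_trajectories(path, trajectories: dict[str, GaitTrajectory],
                      phase: StridePhase | None = None) -> None:
    """Write fitted sum-of-sines coefficients (and stride markers) as JSON."""
    doc = {
        "trajectories": {
            name: {
                "offset": traj.offset,
                "terms": [list(term) for term in traj.terms],
                "periodic": traj.periodic,
                **({"rmse": traj.rmse} if traj.rmse is not None else {}),
            } for name, traj in trajectories.items()},
    }
    if phase is not None:
        doc["phase"] = {"touch_down": phase.touch_down, "lift_off": phase.lift_off}
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def load_trajectories(path) -> tuple[dict[str, GaitTrajectory], StridePhase | None]:
    with open(path) as fh:
        doc = json.load(fh)
    trajectories = {}
    for name, entry in _require(doc, "trajectories", "trajectory file").items():
        trajectories[name] = GaitTrajectory(
            joint=name,
            offset=float(_require(entry, "offset", f"trajectory '{name}'")),
            terms=[tuple(t) for t in _require(entry, "terms", f"trajectory '{name}'")],
            periodic=bool(entry.get("periodic", True)),
            rmse=entry.get("rmse"))
    phase = None
    if "phase" in doc:
        phase = StridePhase(touch_down=doc["phase"]["touch_down"],
                            lift_off=doc["phase"]["lift_off"])
    return trajectories, phase


def write_profile_csv(path, profile) -> None:
    profile.to_dataframe().to_csv(path, index=False)


def write_sensitivity_csv(path, result) -> None:
    result.to_dataframe().to_csv(path, index=False)
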