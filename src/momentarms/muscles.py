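"""Polyline muscle paths fixed to bone frames.

A muscle is an ordered list of attachment points — origin first, insertion
last, optionally with via points in between — each stationary in the local
frame of the bone it attaches to.  The line of action is the polyline
through the world positions of the attachments.  Because every attachment
is bone-fixed, only the *free segment* (the consecutive pair whose bodies
lie on opposite sides of a joint) changes length when that joint moves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import KinematicChain, Pose, joints_between

__all__ = [
    "AttachmentPoint",
    "MusclePath",
    "FreeSegment",
    "world_path",
    "muscle_length",
    "free_segment",
    "spanned_joints",
    "classify_articulation",
]


@dataclass
class AttachmentPoint:
    """A muscle attachment fixed in a bone's local frame (mm)."""

    body: str
    local_position: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        pos = np.asarray(self.local_position, dtype=float)
        if pos.shape != (3,):
            raise ValueError(
                f"attachment '{self.label or self.body}': local_position must be a "
                f"3-vector, got shape {pos.shape}")
        self.local_position = pos


@dataclass
class MusclePath:
    """An ordered polyline muscle path, proximal (origin) to distal (insertion).

    The attachment ordering is load-bearing: it decides which projected
    endpoint is the proximal one in the signed moment-arm formula and
    therefore the sign of the moment arm.
    """

    name: str
    attachments: list[AttachmentPoint]
    group: str | None = None  # cosmetic tag, ignored by all computations

    def __post_init__(self) -> None:
        if len(self.attachments) < 2:
            raise ValueError(f"muscle '{self.name}' needs at least 2 attachments")

    def segments(self) -> list[tuple[int, int]]:
        """Index pairs of consecutive attachments."""
        return [(i, i + 1) for i in range(len(self.attachments) - 1)]


@dataclass
class FreeSegment:
    """The consecutive attachment pair of a muscle that crosses a joint."""

    muscle: str
    proximal_index: int
    distal_index: int
    spanned_joints: list[str]

    def __post_init__(self) -> None:
        if self.distal_index != self.proximal_index + 1:
            raise ValueError("free segment indices must be consecutive")
        if not self.spanned_joints:
            raise ValueError("free segment must span at least one joint")


def world_path(muscle: MusclePath, pose: Pose) -> np.ndarray:
    """World positions of the muscle's attachments, order preserved, (n, 3) mm."""
    points = np.empty((len(muscle.attachments), 3))
    for i, att in enumerate(muscle.attachments):
        try:
            points[i] = pose.transform_point(att.body, att.local_position)
        except KeyError:
            raise KeyError(
                f"muscle '{muscle.name}' attachment {i} references body "
                f"'{att.body}' absent from the pose") from None
    return points


def muscle_length(muscle: MusclePath, pose: Pose) -> float:
    """Total polyline path length L in mm at the given pose."""
    pts = world_path(muscle, pose)
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def free_segment(muscle: MusclePath, chain: KinematicChain, joint: str) -> FreeSegment:
    """The unique consecutive attachment pair of ``muscle`` crossing ``joint``.

    Raises if the muscle does not cross the joint, or crosses it with more
    than one consecutive pair (the single-free-segment model assumed by the
    moment-arm formula does not cover that case).
    """
    chain.joint(joint)
    matches: list[FreeSegment] = []
    for i, k in muscle.segments():
        path = joints_between(chain, muscle.attachments[i].body,
                              muscle.attachments[k].body)
        names = [j.name for j in path]
        if joint in names:
            matches.append(FreeSegment(muscle=muscle.name, proximal_index=i,
                                       distal_index=k, spanned_joints=names))
    if not matches:
        raise ValueError(f"muscle '{muscle.name}' does not cross joint '{joint}'")
    if len(matches) > 1:
        raise ValueError(
            f"ambiguous free segment: muscle '{muscle.name}' crosses joint "
            f"'{joint}' with {len(matches)} attachment pairs")
    return matches[0]


def spanned_joints(muscle: MusclePath, chain: KinematicChain) -> list[str]:
    """All joints crossed by any consecutive attachment pair, in chain order."""
    crossed: set[str] = set()
    for i, k in muscle.segments():
        path = joints_between(chain, muscle.attachments[i].body,
                              muscle.attachments[k].body)
        crossed.update(j.name for j in path)
    return [name for name in chain.joint_names() if name in crossed]


def classify_articulation(muscle: MusclePath, chain: KinematicChain) -> str:
    """'monoarticular', 'biarticular', 'multiarticular' or 'non-articular'.

    A muscle whose attachments all sit on one body crosses no joint and
    cannot produce torque; that is almost certainly a model-definition
    mistake, so it is flagged with a warning rather than an error.
    """
    n = len(spanned_joints(muscle, chain))
    if n == 0:
        warnings.warn(
            f"muscle '{muscle.name}' crosses no joint (non-articular); "
            "check the model definition", stacklevel=2)
        return "non-articular"
    if n == 1:
        return "monoarticular"
    if n == 2:
        return "biarticular"
    return "multiarticular"
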