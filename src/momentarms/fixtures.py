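"""Synthetic limb fixtures with known, closed-form moment-arm behaviour.

Three generators make every part of the engine testable without any
external dataset:

``pulley``
    A two-joint serial linkage whose muscle spans the distal joint while
    the proximal joint is swept.  The spanned assembly co-rotates
    rigidly, so the moment arm about the distal joint is constant by
    construction — the polyline analogue of an idealised pulley of fixed
    radius (a straight two-point segment rotating about its own joint
    cannot hold a nonzero constant arm).

``planar_two_body``
    A single hinge at the origin, axis +z, with a fixed attachment at
    (-a, d, 0) and an attachment at (b, d, 0) on the rotating body.  The
    signed arm has a closed form from the two endpoint positions.

``rat_like``
    A pelvis-femur-tibia-foot sagittal chain with hinge hip, knee and
    ankle, mono- and biarticular polyline muscles, and a periodic
    sum-of-sines gait preset.  The geometry is *synthetic*: invented,
    plausible proportions around a 35.75 mm femur, never anatomical
    coordinates.  Each muscle runs in its own parasagittal plane
    (constant mediolateral offset), so the projected moment arm equals
    the tendon-excursion arm exactly.  Attachments are jittered by a
    seeded +/-2 mm in-plane perturbation, resampled if any free segment
    approaches degeneracy anywhere within the joint limits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import (HingeJoint, BodySegment, KinematicChain,
                   forward_kinematics, joint_frame)
from .gait import GaitTrajectory, StridePhase
from .momentarm import project_free_segment
from .muscles import AttachmentPoint, MusclePath, free_segment, spanned_joints

__all__ = ["FixtureSpec", "Fixture", "generate_fixture", "closed_form_moment_arm"]

TWO_PI = 2.0 * math.pi

#: default femur length (mm) of the rat-like fixture
DEFAULT_FEMUR_LENGTH = 35.75


@dataclass
class FixtureSpec:
    """Parameters of a synthetic fixture.

    ``kind`` is 'pulley', 'planar_two_body' or 'rat_like'.  ``seed`` fixes
    every sampled quantity; identical specs produce identical fixtures.
    """

    kind: str
    seed: int = 0
    femur_length: float = DEFAULT_FEMUR_LENGTH
    pulley_distance: float = 2.0          # constant arm d of the pulley, mm
    planar_params: tuple[float, float, float] = (10.0, 10.0, 5.0)  # (a, b, d) mm
    jitter_mm: float = 2.0                # rat_like in-plane attachment jitter
    tibia_length: float = 40.0

    def __post_init__(self) -> None:
        for name in ("femur_length", "pulley_distance", "tibia_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.jitter_mm < 0:
            raise ValueError("jitter_mm must be >= 0")


@dataclass
class Fixture:
    """A generated model: chain, muscles, gait trajectories, stride phase."""

    chain: KinematicChain
    muscles: list[MusclePath]
    trajectories: dict[str, GaitTrajectory]
    phase: StridePhase

    def muscle(self, name: str) -> MusclePath:
        for m in self.muscles:
            if m.name == name:
                return m
        raise KeyError(f"no muscle '{name}' in fixture")


def _pulley_fixture(spec: FixtureSpec) -> Fixture:
    d = spec.pulley_distance
    bodies = [BodySegment("base"), BodySegment("link1"), BodySegment("link2")]
    joints = [
        HingeJoint("drive", "base", "link1", center_local=(0.0, 0.0, 0.0),
                   axis_local=(0.0, 0.0, 1.0), angle_limits=(-45.0, 45.0)),
        HingeJoint("pulley", "link1", "link2", center_local=(30.0, 0.0, 0.0),
                   axis_local=(0.0, 0.0, 1.0), angle_limits=(-45.0, 45.0)),
    ]
    chain = KinematicChain(bodies, joints)
    # both endpoints sit at perpendicular distance d below the pulley axis;
    # the proximal-first sign convention makes the engine arm +d
    belt = MusclePath("belt", [
        AttachmentPoint("link1", (30.0, -d, 0.0), "origin"),
        AttachmentPoint("link2", (80.0, -d, 0.0), "insertion"),
    ])
    trajectories = {
        "drive": GaitTrajectory("drive", offset=0.0, terms=[(30.0, TWO_PI, 0.0)]),
        "pulley": GaitTrajectory("pulley", offset=0.0, terms=[(0.0, TWO_PI, 0.0)]),
    }
    return Fixture(chain, [belt], trajectories, StridePhase(0.0, 0.6))


def _planar_two_body_fixture(spec: FixtureSpec) -> Fixture:
    a, b, d = spec.planar_params
    bodies = [BodySegment("base"), BodySegment("link")]
    joints = [HingeJoint("hinge", "base", "link", center_local=(0.0, 0.0, 0.0),
                         axis_local=(0.0, 0.0, 1.0), angle_limits=(-60.0, 60.0))]
    chain = KinematicChain(bodies, joints)
    cord = MusclePath("cord", [
        AttachmentPoint("base", (-a, d, 0.0), "origin"),
        AttachmentPoint("link", (b, d, 0.0), "insertion"),
    ])
    trajectories = {
        "hinge": GaitTrajectory("hinge", offset=0.0, terms=[(30.0, TWO_PI, 0.0)]),
    }
    return Fixture(chain, [cord], trajectories, StridePhase(0.0, 0.6))


# rat_like base geometry: x cranial, y dorsal (limb hangs along -y),
# z mediolateral.  Per-muscle entries: list of (body, x, y) plus a constant
# mediolateral lane z; all jitter is in-plane so every free segment stays
# parasagittal.
_RAT_MUSCLES: list[tuple[str, float, list[tuple[str, float, float]]]] = [
    ("hip_flexor", 1.5, [("pelvis", -12.0, 6.0), ("femur", 4.0, -9.0)]),
    ("hip_extensor", -3.0, [("pelvis", -14.0, -2.0), ("femur", -5.0, -16.0)]),
    ("knee_extensor", 2.5, [("femur", 4.0, -16.0), ("tibia", 5.0, -44.0)]),
    ("ankle_dorsiflexor", -1.5, [("tibia", 4.0, -50.0), ("tibia", 4.0, -72.0),
                                 ("foot", 12.0, -80.0)]),
    ("hamstring", -2.5, [("pelvis", -14.0, -4.0), ("tibia", -5.0, -42.0)]),
    ("gastrocnemius", 3.5, [("femur", -4.0, -30.0), ("foot", -7.0, -79.0)]),
    # via point on the pelvis keeps the joint-crossing segment single, so the
    # hip and knee arms stay genuinely coupled through both joints
    ("rectus", 0.5, [("pelvis", -6.0, 8.0), ("pelvis", -2.0, 2.0),
                     ("tibia", 6.0, -44.0)]),
]

_RAT_GAIT: dict[str, tuple[float, list[tuple[float, float, float]]]] = {
    "hip": (-2.0, [(18.0, TWO_PI, 0.0), (3.0, 2 * TWO_PI, 1.2)]),
    "knee": (-20.0, [(22.0, TWO_PI, 2.1), (4.0, 2 * TWO_PI, 0.5)]),
    "ankle": (8.0, [(14.0, TWO_PI, 4.0), (5.0, 2 * TWO_PI, 2.6)]),
}

#: minimum acceptable ||p_f x j|| (mm) for any free segment at any pose
#: within joint limits; jittered geometry violating it is resampled
_DEGENERACY_GUARD = 0.1


def _rat_chain(spec: FixtureSpec) -> KinematicChain:
    knee_y = -spec.femur_length
    ankle_y = knee_y - spec.tibia_length
    bodies = [
        BodySegment("pelvis"),
        BodySegment("femur", reference_length=spec.femur_length),
        BodySegment("tibia", reference_length=spec.tibia_length),
        BodySegment("foot"),
    ]
    joints = [
        HingeJoint("hip", "pelvis", "femur", center_local=(0.0, 0.0, 0.0),
                   axis_local=(0.0, 0.0, 1.0), angle_limits=(-40.0, 40.0),
                   zero_pose_note="0 deg = femur along -y; cranial rotation positive"),
        HingeJoint("knee", "femur", "tibia", center_local=(0.0, knee_y, 0.0),
                   axis_local=(0.0, 0.0, 1.0), angle_limits=(-70.0, 30.0),
                   zero_pose_note="0 deg = tibia collinear with femur"),
        HingeJoint("ankle", "tibia", "foot", center_local=(0.0, ankle_y, 0.0),
                   axis_local=(0.0, 0.0, 1.0), angle_limits=(-45.0, 45.0),
                   zero_pose_note="0 deg = foot along +x"),
    ]
    return KinematicChain(bodies, joints)


def _min_segment_norm(chain: KinematicChain, muscle: MusclePath,
                      n_per_joint: int = 5) -> float:
    """Smallest ||p_f x j|| over all spanned joints and a joint-limit grid."""
    grids = [np.linspace(*j.angle_limits, n_per_joint) for j in chain.joints]
    names = chain.joint_names()
    pairs = [(jname, free_segment(muscle, chain, jname))
             for jname in spanned_joints(muscle, chain)]
    worst = math.inf
    for combo in np.array(np.meshgrid(*grids)).reshape(len(grids), -1).T:
        angles = dict(zip(names, map(float, combo)))
        pose = forward_kinematics(chain, angles)
        from .muscles import world_path
        pts = world_path(muscle, pose)
        for jname, seg in pairs:
            frame = joint_frame(chain, pose, jname)
            proj = project_free_segment(pts[seg.proximal_index],
                                        pts[seg.distal_index], frame)
            worst = min(worst, float(np.linalg.norm(
                np.cross(proj.p_f, frame.axis_world))))
    return worst


def _rat_like_fixture(spec: FixtureSpec) -> Fixture:
    chain = _rat_chain(spec)
    rng = np.random.default_rng(spec.seed)
    scale = spec.femur_length / DEFAULT_FEMUR_LENGTH

    muscles: list[MusclePath] = []
    for name, lane, points in _RAT_MUSCLES:
        for attempt in range(100):
            attachments = []
            for idx, (body, x, y) in enumerate(points):
                dx, dy = rng.uniform(-spec.jitter_mm, spec.jitter_mm, size=2)
                label = ("origin" if idx == 0
                         else "insertion" if idx == len(points) - 1
                         else f"via{idx}")
                attachments.append(AttachmentPoint(
                    body, (x * scale + dx, y * scale + dy, lane), label))
            candidate = MusclePath(name, attachments)
            if _min_segment_norm(chain, candidate) >= _DEGENERACY_GUARD:
                muscles.append(candidate)
                break
        else:  # pragma: no cover - base geometry keeps segments long
            raise RuntimeError(f"could not place non-degenerate muscle '{name}'")

    trajectories = {
        j: GaitTrajectory(j, offset=off, terms=list(terms))
        for j, (off, terms) in _RAT_GAIT.items()}
    return Fixture(chain, muscles, trajectories, StridePhase(0.0, 0.6))


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Build the fixture described by ``spec``; deterministic per spec+seed."""
    if spec.kind == "pulley":
        return _pulley_fixture(spec)
    if spec.kind == "planar_two_body":
        return _planar_two_body_fixture(spec)
    if spec.kind == "rat_like":
        return _rat_like_fixture(spec)
    raise ValueError(f"unknown fixture kind '{spec.kind}'")


def closed_form_moment_arm(kind: str, params: dict, theta_deg: float) -> float:
    """Analytic signed moment arm of the toy fixtures, for cross-checking.

    ``pulley``: the arm about the spanned joint is the constant
    perpendicular offset ``d`` regardless of the swept proximal angle.

    ``planar_two_body``: fixed proximal attachment (-a, d), rotating
    attachment at local (b, d), hinge at the origin with axis +z.  The
    signed perpendicular distance from the origin to the chord through
    the two endpoints P1, P2 is the 2D determinant formula

        r = (x1 * y2 - y1 * x2) / ||P2 - P1||,

    which carries the same orientation convention as the engine
    (proximal endpoint first, right-hand rotation about +z).
    """
    if kind == "pulley":
        return float(params["d"])
    if kind == "planar_two_body":
        a, b, d = params["a"], params["b"], params["d"]
        th = math.radians(theta_deg)
        x1, y1 = -a, d
        x2 = b * math.cos(th) - d * math.sin(th)
        y2 = b * math.sin(th) + d * math.cos(th)
        chord = math.hypot(x2 - x1, y2 - y1)
        if chord < 1e-12:
            raise ValueError("coincident endpoints")
        return (x1 * y2 - y1 * x2) / chord
    raise ValueError(f"unsupported fixture kind '{kind}'")
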