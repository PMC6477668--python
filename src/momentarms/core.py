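"""Rigid-body limb chains articulated by ideal hinge joints.

A limb is modelled as a rooted open chain of rigid segments (pelvis, femur,
tibia, foot, ...) connected by single-axis hinge joints.  Every body carries
a local coordinate frame; at the reference (all-zero-angle) pose every body
frame coincides with the world frame, so local coordinates double as
reference-pose world coordinates.  Rotating a joint by an angle rotates the
entire distal subtree about the joint's world-frame axis through its
world-frame centre, following the right-hand rule.

All lengths are millimetres and all angles at the public interfaces are
degrees; conversion to radians happens internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BodySegment",
    "HingeJoint",
    "KinematicChain",
    "Pose",
    "JointFrame",
    "forward_kinematics",
    "joint_frame",
    "joints_between",
]


def _as_vec3(value, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite, got {arr}")
    return arr


def rotation_about_axis(center: np.ndarray, axis_unit: np.ndarray,
                        angle_rad: float) -> np.ndarray:
    """Homogeneous 4x4 rotation by ``angle_rad`` about the line through
    ``center`` with direction ``axis_unit`` (right-hand rule)."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.from_rotvec(angle_rad * axis_unit).as_matrix()
    transform = np.eye(4)
    transform[:3, :3] = rot
    transform[:3, 3] = center - rot @ center
    return transform


def apply_transform(transform: np.ndarray, point: np.ndarray) -> np.ndarray:
    """Apply a homogeneous 4x4 rigid transform to a 3-point."""
    return transform[:3, :3] @ point + transform[:3, 3]


@dataclass
class BodySegment:
    """A rigid bone segment.

    Parameters
    ----------
    name
        Unique identifier within a chain (e.g. ``"femur"``).
    parent_joint
        Name of the hinge joint whose rotation carries this body, or
        ``None`` for the root segment.  Optional metadata; the chain
        cross-checks it against its joint list when present.
    reference_length
        Characteristic length in mm used for size normalisation
        (typically the femur length).  Must be positive when given.
    """

    name: str
    parent_joint: str | None = None
    reference_length: float | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("body name must be non-empty")
        if self.reference_length is not None and self.reference_length <= 0:
            raise ValueError(
                f"body '{self.name}': reference_length must be > 0, "
                f"got {self.reference_length}")


@dataclass
class HingeJoint:
    """A single-axis revolute joint between two bodies.

    The joint centre and axis are expressed in the *parent* body's frame
    and are stationary in it.  For an ideal hinge the centre lies on the
    rotation axis, so expressing it in the parent or the child frame
    yields the same world-frame centre at every pose.

    ``zero_pose_note`` is free text documenting the anatomical convention
    of the zero angle (e.g. "0 deg = femur vertical, flexion positive");
    the engine itself is convention-agnostic.
    """

    name: str
    parent_body: str
    child_body: str
    center_local: np.ndarray
    axis_local: np.ndarray
    angle_limits: tuple[float, float] = (-180.0, 180.0)
    zero_pose_note: str = ""

    def __post_init__(self) -> None:
        self.center_local = _as_vec3(self.center_local, f"joint '{self.name}' center_local")
        self.axis_local = _as_vec3(self.axis_local, f"joint '{self.name}' axis_local")
        norm = float(np.linalg.norm(self.axis_local))
        if norm < 1e-12:
            raise ValueError(f"joint '{self.name}': axis_local has zero norm")
        lo, hi = self.angle_limits
        if not lo < hi:
            raise ValueError(
                f"joint '{self.name}': angle_limits min must be < max, got ({lo}, {hi})")
        self.angle_limits = (float(lo), float(hi))

    @property
    def axis_unit(self) -> np.ndarray:
        return self.axis_local / np.linalg.norm(self.axis_local)


@dataclass
class KinematicChain:
    """A rooted open chain (tree) of bodies connected by hinge joints."""

    bodies: list[BodySegment]
    joints: list[HingeJoint]
    _body_map: dict[str, BodySegment] = field(init=False, repr=False)
    _joint_map: dict[str, HingeJoint] = field(init=False, repr=False)
    _parent_joint: dict[str, HingeJoint] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        names = [b.name for b in self.bodies]
        if len(set(names)) != len(names):
            raise ValueError("body names must be unique")
        jnames = [j.name for j in self.joints]
        if len(set(jnames)) != len(jnames):
            raise ValueError("joint names must be unique")
        self._body_map = {b.name: b for b in self.bodies}
        self._joint_map = {j.name: j for j in self.joints}

        self._parent_joint = {}
        for j in self.joints:
            for b in (j.parent_body, j.child_body):
                if b not in self._body_map:
                    raise ValueError(f"joint '{j.name}' references unknown body '{b}'")
            if j.child_body in self._parent_joint:
                raise ValueError(
                    f"body '{j.child_body}' is the child of more than one joint")
            self._parent_joint[j.child_body] = j

        roots = [b.name for b in self.bodies if b.name not in self._parent_joint]
        if len(roots) != 1:
            raise ValueError(f"chain must have exactly one root body, found {roots}")
        self._root = roots[0]

        # detect cycles / disconnected parts and cache depth for path queries
        self._depth: dict[str, int] = {}
        for b in self.bodies:
            seen: set[str] = set()
            name, depth = b.name, 0
            while name in self._parent_joint:
                if name in seen:
                    raise ValueError(f"cycle detected through body '{b.name}'")
                seen.add(name)
                name = self._parent_joint[name].parent_body
                depth += 1
            if name != self._root:
                raise ValueError(f"body '{b.name}' is not connected to the root")
            self._depth[b.name] = depth

        for b in self.bodies:
            declared = b.parent_joint
            actual = self._parent_joint.get(b.name)
            if declared is not None and (actual is None or actual.name != declared):
                raise ValueError(
                    f"body '{b.name}' declares parent_joint '{declared}' but the "
                    f"joint list implies {actual.name if actual else None!r}")

    @property
    def root(self) -> str:
        return self._root

    def body(self, name: str) -> BodySegment:
        try:
            return self._body_map[name]
        except KeyError:
            raise KeyError(f"unknown body '{name}'") from None

    def joint(self, name: str) -> HingeJoint:
        try:
            return self._joint_map[name]
        except KeyError:
            raise KeyError(f"unknown joint '{name}'") from None

    def joint_names(self) -> list[str]:
        return [j.name for j in self.joints]

    def parent_joint_of(self, body: str) -> HingeJoint | None:
        self.body(body)
        return self._parent_joint.get(body)

    def path_to_root(self, body: str) -> list[HingeJoint]:
        """Joints on the path from ``body`` up to the root, nearest first."""
        self.body(body)
        out = []
        name = body
        while name in self._parent_joint:
            j = self._parent_joint[name]
            out.append(j)
            name = j.parent_body
        return out


@dataclass
class Pose:
    """Joint angles plus the world transform of every body.

    ``world_transforms`` maps body name to a homogeneous 4x4 proper rigid
    motion; at the reference pose all transforms are the identity (up to
    the optional base transform applied to the root).
    """

    joint_angles: dict[str, float]
    world_transforms: dict[str, np.ndarray]

    def transform(self, body: str) -> np.ndarray:
        try:
            return self.world_transforms[body]
        except KeyError:
            raise KeyError(f"pose has no transform for body '{body}'") from None

    def transform_point(self, body: str, local_point) -> np.ndarray:
        """World position of a point given in ``body``'s local frame."""
        return apply_transform(self.transform(body), np.asarray(local_point, float))


@dataclass
class JointFrame:
    """A joint's world-frame centre and unit axis at a specific pose."""

    joint_name: str
    center_world: np.ndarray
    axis_world: np.ndarray

    def __post_init__(self) -> None:
        self.center_world = _as_vec3(self.center_world, "center_world")
        axis = _as_vec3(self.axis_world, "axis_world")
        norm = float(np.linalg.norm(axis))
        if norm < 1e-12:
            raise ValueError("axis_world has zero norm")
        self.axis_world = axis / norm


def forward_kinematics(chain: KinematicChain, angles: dict[str, float], *,
                       base_transform: np.ndarray | None = None,
                       ignore_limits: bool = False) -> Pose:
    """Compose world transforms for every body at the given joint angles.

    Parameters
    ----------
    chain
        The kinematic chain.
    angles
        Map joint name -> angle in degrees.  Every joint of the chain must
        be present; unknown names are rejected to catch typos.
    base_transform
        Optional 4x4 rigid transform applied to the root body (and hence
        the whole limb); defaults to the identity.
    ignore_limits
        When True, angles outside a joint's limits are accepted.  The
        default enforces limits and raises naming the offending joint.
    """
    joint_names = set(chain.joint_names())
    missing = sorted(joint_names - set(angles))
    if missing:
        raise ValueError(f"missing joint angle(s) for {missing}")
    unknown = sorted(set(angles) - joint_names)
    if unknown:
        raise ValueError(f"angles given for unknown joint(s) {unknown}")

    if not ignore_limits:
        for j in chain.joints:
            theta = angles[j.name]
            lo, hi = j.angle_limits
            if not (lo <= theta <= hi):
                raise ValueError(
                    f"joint '{j.name}' angle {theta:g} deg outside limits "
                    f"({lo:g} deg, {hi:g} deg)")

    transforms: dict[str, np.ndarray] = {}
    root_t = np.eye(4) if base_transform is None else np.asarray(base_transform, float)
    transforms[chain.root] = root_t

    # joints are re-ordered so a parent body's transform is always ready
    pending = list(chain.joints)
    while pending:
        progressed = False
        for j in list(pending):
            if j.parent_body in transforms:
                local = rotation_about_axis(
                    j.center_local, j.axis_unit, math.radians(angles[j.name]))
                transforms[j.child_body] = transforms[j.parent_body] @ local
                pending.remove(j)
                progressed = True
        if not progressed:  # pragma: no cover - chain validation prevents this
            raise ValueError("chain joints do not form a connected tree")

    return Pose(joint_angles=dict(angles), world_transforms=transforms)


def joint_frame(chain: KinematicChain, pose: Pose, joint: str) -> JointFrame:
    """World-frame centre and unit axis of ``joint`` at ``pose``.

    The centre and axis are fixed in the parent body's frame, so they are
    mapped through the parent's world transform.  For an ideal hinge the
    child transform gives the identical centre (the centre lies on the
    axis) and the identical axis direction.
    """
    j = chain.joint(joint)
    parent_t = pose.transform(j.parent_body)
    center = apply_transform(parent_t, j.center_local)
    axis = parent_t[:3, :3] @ j.axis_unit
    return JointFrame(joint_name=j.name, center_world=center, axis_world=axis)


def joints_between(chain: KinematicChain, body_a: str, body_b: str) -> list[HingeJoint]:
    """Joints on the unique tree path between two bodies.

    The list is ordered along the walk from ``body_a`` to ``body_b`` (for
    a serial limb queried proximal-to-distal this is proximal-first);
    swapping the arguments reverses it.  Returns [] when the bodies
    coincide.
    """
    up_a = chain.path_to_root(body_a)
    up_b = chain.path_to_root(body_b)
    # joints in both root paths lie above the lowest common ancestor body
    names_a = {j.name for j in up_a}
    names_b = {j.name for j in up_b}
    a_leg = [j for j in up_a if j.name not in names_b]
    b_leg = [j for j in up_b if j.name not in names_a]
    return a_leg + list(reversed(b_leg))
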