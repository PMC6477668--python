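r"""Signed muscle moment arms about hinge joints, plus two independent oracles.

The moment arm of a muscle about a hinge joint is computed by vector
analysis on the muscle's free segment — the single consecutive attachment
pair whose endpoints lie on opposite sides of the joint:

1. Both endpoints, re-expressed relative to the joint centre, are projected
   onto the plane through the joint centre normal to the unit joint axis
   :math:`\hat{\jmath}`:

   .. math:: p_{proj,i} = p_i - (p_i \cdot \hat{\jmath})\,\hat{\jmath}

2. The projected segment vector is the difference of the projections:

   .. math:: p_f = p_{proj,2} - p_{proj,1}

3. The signed scalar moment arm is

   .. math:: r = p_{proj,1} \cdot \frac{p_f \times \hat{\jmath}}
                                        {\lVert p_f \times \hat{\jmath}\rVert}

|r| is the perpendicular distance in the joint plane from the joint centre
to the projected line of action.  Sign convention with proximal-first
attachment ordering and right-hand-rule joint rotation: for a free segment
lying in the joint plane, r equals +dL/dtheta, the rate of muscle-length
change per radian of joint rotation; positive r therefore marks a muscle
that lengthens as the joint angle increases (its tension drives the joint
towards negative angles).  For a free segment oblique to the joint plane
the geometric r exceeds the effective (tendon-excursion) arm by the factor
L / ||p_f||.

Two independent oracles validate the formula: a brute-force point-to-line
distance minimisation (magnitude) and the classical tendon-excursion
identity -dL/dtheta (magnitude and sign).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .core import JointFrame, KinematicChain, Pose, forward_kinematics
from .muscles import FreeSegment, MusclePath, free_segment, muscle_length, world_path

__all__ = [
    "DEGENERACY_EPS",
    "FreeSegmentProjection",
    "MomentArmSample",
    "project_point",
    "project_free_segment",
    "signed_moment_arm",
    "moment_arm",
    "point_line_distance_oracle",
    "tendon_excursion_oracle",
]

# Threshold on ||p_f x j|| below which the projected free segment is treated
# as degenerate (segment parallel to the axis, or zero length after
# projection): far below any anatomical scale, above double-precision noise.
DEGENERACY_EPS = 1e-9


@dataclass
class FreeSegmentProjection:
    """Projected free-segment endpoints in joint-centred coordinates (mm)."""

    p_proj_1: np.ndarray
    p_proj_2: np.ndarray

    @property
    def p_f(self) -> np.ndarray:
        return self.p_proj_2 - self.p_proj_1


@dataclass
class MomentArmSample:
    """One signed moment arm with the pose context it was computed in.

    ``theta_deg`` is set for isolated-joint sweeps, ``t`` (normalised
    stride time) for stepping motion.  ``angles`` records every joint
    angle of the pose, because a biarticular muscle's moment arm about one
    joint depends on the adjacent joint's angle as well.
    """

    muscle: str
    joint: str
    r: float
    angles: dict[str, float]
    theta_deg: float | None = None
    t: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.r):
            raise ValueError("moment arm must be finite")


def project_point(p, frame: JointFrame) -> np.ndarray:
    """Project a world point onto the joint plane, in joint-centred coordinates.

    Returns (p - centre) minus its component along the unit joint axis.
    The result is orthogonal to the axis and the operation is idempotent.
    """
    rel = np.asarray(p, float) - frame.center_world
    axis = frame.axis_world
    return rel - (rel @ axis) * axis


def project_free_segment(p1, p2, frame: JointFrame) -> FreeSegmentProjection:
    return FreeSegmentProjection(project_point(p1, frame), project_point(p2, frame))


def signed_moment_arm(p1, p2, frame: JointFrame) -> float:
    """Signed moment arm from two world-frame free-segment endpoints.

    ``p1`` must be the proximal endpoint and ``p2`` the distal one; swapping
    them flips the sign.  Raises on a degenerate projected segment.
    """
    proj = project_free_segment(p1, p2, frame)
    n = np.cross(proj.p_f, frame.axis_world)
    norm = float(np.linalg.norm(n))
    if norm < DEGENERACY_EPS:
        raise ValueError(
            f"degenerate free segment about joint '{frame.joint_name}': "
            f"projected segment has ||p_f x j|| = {norm:.3e} mm")
    return float(proj.p_proj_1 @ (n / norm))


def moment_arm(muscle: MusclePath, pose: Pose, chain: KinematicChain,
               joint: str, segment: FreeSegment | None = None) -> float:
    """Signed moment arm r (mm) of ``muscle`` about ``joint`` at ``pose``.

    The free segment is located automatically unless supplied.
    """
    from .core import joint_frame as _joint_frame

    if segment is None:
        segment = free_segment(muscle, chain, joint)
    frame = _joint_frame(chain, pose, joint)
    pts = world_path(muscle, pose)
    return signed_moment_arm(pts[segment.proximal_index],
                             pts[segment.distal_index], frame)


def point_line_distance_oracle(p1, p2, center) -> float:
    """Unsigned distance from ``center`` to the infinite line through p1, p2.

    Deliberately naive: scalar minimisation of ||center - (p1 + t (p2-p1))||
    over the line parameter t, with no cross products, so it is an
    independent check of the moment-arm magnitude.
    """
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    center = np.asarray(center, float)
    d = p2 - p1
    if np.linalg.norm(d) < 1e-12:
        raise ValueError("coincident points do not define a line")

    def dist2(t: float) -> float:
        delta = center - (p1 + t * d)
        return float(delta @ delta)

    res = minimize_scalar(dist2, bounds=(-1e6, 1e6), method="bounded",
                          options={"xatol": 1e-10, "maxiter": 1000})
    return math.sqrt(max(res.fun, 0.0))


def tendon_excursion_oracle(muscle: MusclePath, chain: KinematicChain,
                            joint: str, angles: dict[str, float],
                            h: float = 0.01) -> float:
    """Effective moment arm -dL/dtheta (mm per radian of joint rotation).

    Central finite difference of the total muscle-tendon length with
    respect to the angle of ``joint`` (step ``h`` in degrees, default
    0.01), all other joints held fixed.  Classical identity: a muscle's
    torque per unit tension about a hinge equals the negative derivative
    of its length with respect to the joint angle.  Used as an oracle for
    the vector formula; with proximal-first ordering the two agree as
    r = -(-dL/dtheta) for in-plane free segments.

    The muscle must cross the joint exactly once.
    """
    free_segment(muscle, chain, joint)  # validates single crossing
    if joint not in angles:
        raise ValueError(f"angles must include swept joint '{joint}'")

    def length_at(theta: float) -> float:
        a = dict(angles)
        a[joint] = theta
        pose = forward_kinematics(chain, a, ignore_limits=True)
        return muscle_length(muscle, pose)

    theta0 = angles[joint]
    h_rad = math.radians(h)
    return -(length_at(theta0 + h) - length_at(theta0 - h)) / (2.0 * h_rad)
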