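"""Moment-arm profiles, sensitivity analyses and derived deliverables.

Builds on the core engine to produce the quantities a modeller actually
inspects: isolated-joint sweeps, stepping (multijoint) profiles over a
normalised stride, moment-arm-versus-length loops, femur-length-normalised
profiles, reachable (theta1, theta2, r) surfaces for biarticular muscles,
and +/- 1 mm attachment-perturbation sensitivity runs.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import KinematicChain, forward_kinematics
from .gait import GaitTrajectory, StridePhase, pose_at
from .momentarm import MomentArmSample, moment_arm
from .muscles import MusclePath, free_segment, muscle_length, spanned_joints

__all__ = [
    "MomentArmProfile",
    "PerturbationSpec",
    "SensitivityResult",
    "SurfaceGrid",
    "MomentArmLengthLoop",
    "isolated_joint_profile",
    "stepping_profile",
    "moment_arm_vs_length",
    "sensitivity_analysis",
    "normalize_profile",
    "reachable_surface",
]


@dataclass
class MomentArmProfile:
    """Sampled moment arms for one muscle-joint pair.

    ``mode`` is 'isolated' (single-joint sweep, samples ordered by sweep
    angle) or 'stepping' (multijoint gait, samples ordered by stride time).
    ``normalization`` is 'none' or 'femur_length'; in the latter case
    ``reference_length`` records the length (mm) the arms were divided by.
    """

    muscle: str
    joint: str
    mode: str
    samples: list[MomentArmSample]
    normalization: str = "none"
    reference_length: float | None = None
    sweep_joint: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("isolated", "stepping"):
            raise ValueError(f"unknown profile mode '{self.mode}'")
        for s in self.samples:
            if s.muscle != self.muscle or s.joint != self.joint:
                raise ValueError("all samples must share the profile's muscle and joint")

    @property
    def r(self) -> np.ndarray:
        """Moment arms as an array, in sample order."""
        return np.array([s.r for s in self.samples])

    @property
    def abscissa(self) -> np.ndarray:
        """Sweep angles (isolated) or stride times (stepping)."""
        if self.mode == "isolated":
            return np.array([s.theta_deg for s in self.samples])
        return np.array([s.t for s in self.samples])

    def to_dataframe(self) -> pd.DataFrame:
        joint_names = sorted({k for s in self.samples for k in s.angles})
        rows = []
        for s in self.samples:
            row = {
                "muscle": s.muscle,
                "joint": s.joint,
                "mode": self.mode,
                "t_or_theta_deg": s.t if self.mode == "stepping" else s.theta_deg,
            }
            for j in joint_names:
                row[f"angle_{j}_deg"] = s.angles[j]
            if self.normalization == "none":
                row["r_mm"] = s.r
                row["r_normalized"] = ""
            else:
                row["r_mm"] = ""
                row["r_normalized"] = s.r
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class PerturbationSpec:
    """A +/- attachment perturbation for sensitivity analysis.

    ``attachment_index`` addresses one end of the free segment of the
    muscle about the studied joint; ``direction`` is a unit vector in that
    attachment's body-local frame; ``magnitude`` is the displacement in mm
    (applied as a +/- pair, default 1 mm).
    """

    muscle: str
    attachment_index: int
    direction: np.ndarray
    magnitude: float = 1.0

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        if d.shape != (3,):
            raise ValueError("direction must be a 3-vector")
        norm = float(np.linalg.norm(d))
        if abs(norm - 1.0) > 1e-6:
            raise ValueError(f"direction must be unit-norm, got |d| = {norm:.6g}")
        self.direction = d
        if self.magnitude < 0:
            raise ValueError("magnitude must be >= 0")


@dataclass
class SensitivityResult:
    """Baseline and +/- perturbed profiles on an identical sweep."""

    spec: PerturbationSpec
    baseline: MomentArmProfile
    perturbed_plus: MomentArmProfile
    perturbed_minus: MomentArmProfile
    max_abs_deviation: float

    def to_dataframe(self) -> pd.DataFrame:
        theta = self.baseline.abscissa
        r0 = self.baseline.r
        rp = self.perturbed_plus.r
        rm = self.perturbed_minus.r
        return pd.DataFrame({
            "theta_deg": theta,
            "r_baseline_mm": r0,
            "r_plus_mm": rp,
            "r_minus_mm": rm,
            "deviation_plus_mm": rp - r0,
            "deviation_minus_mm": rm - r0,
        })


@dataclass
class SurfaceGrid:
    """Moment arm on a (theta1, theta2) grid for a biarticular muscle.

    ``r`` is NaN outside the mask; the mask keeps grid cells within a
    stated distance of the joint-angle combinations actually visited by
    the gait, mirroring the idea that only angle pairs reachable within
    physiological walking are meaningful.
    """

    muscle: str
    joint: str
    joint_pair: tuple[str, str]
    theta1: np.ndarray
    theta2: np.ndarray
    r: np.ndarray
    mask: np.ndarray


@dataclass
class MomentArmLengthLoop:
    """Moment arm versus muscle length over one stride, optionally min-max
    normalised, with stride-phase markers."""

    muscle: str
    joint: str
    t: np.ndarray
    length: np.ndarray
    r: np.ndarray
    normalized: bool
    constant_length: bool = False
    phase: StridePhase | None = None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "length": self.length, "r": self.r})


def _sweep_values(sweep: tuple[float, float, float]) -> np.ndarray:
    lo, hi, step = sweep
    if step <= 0:
        raise ValueError("sweep step must be > 0")
    if hi < lo:
        raise ValueError("sweep max must be >= min")
    n = int(round((hi - lo) / step))
    vals = lo + step * np.arange(n + 1)
    return vals[vals <= hi + 1e-9]


def isolated_joint_profile(chain: KinematicChain, muscle: MusclePath, joint: str,
                           sweep: tuple[float, float, float],
                           fixed_angles: dict[str, float] | None = None,
                           sweep_joint: str | None = None) -> MomentArmProfile:
    """Moment arm of ``muscle`` about ``joint`` over a single-joint sweep.

    ``sweep`` is (min_deg, max_deg, step_deg), endpoints inclusive.  All
    joints other than the swept one are held at ``fixed_angles`` (default
    0 deg, the usual convention for isolated-joint validation sweeps).
    ``sweep_joint`` defaults to ``joint``; sweeping a different joint is
    useful for probing how a profile depends on an adjacent joint, or for
    rigid-co-rotation fixtures with a constant arm by construction.
    """
    segment = free_segment(muscle, chain, joint)
    swept = sweep_joint or joint
    chain.joint(swept)
    base = {name: 0.0 for name in chain.joint_names()}
    if fixed_angles:
        unknown = sorted(set(fixed_angles) - set(base))
        if unknown:
            raise ValueError(f"fixed_angles given for unknown joint(s) {unknown}")
        base.update(fixed_angles)

    lo, hi = chain.joint(swept).angle_limits
    values = _sweep_values(sweep)
    if values.size and (values[0] < lo - 1e-9 or values[-1] > hi + 1e-9):
        raise ValueError(
            f"sweep ({values[0]:g}, {values[-1]:g}) exceeds joint '{swept}' "
            f"limits ({lo:g}, {hi:g})")

    samples = []
    for theta in values:
        angles = dict(base)
        angles[swept] = float(theta)
        pose = forward_kinematics(chain, angles)
        r = moment_arm(muscle, pose, chain, joint, segment=segment)
        samples.append(MomentArmSample(muscle=muscle.name, joint=joint, r=r,
                                       angles=angles, theta_deg=float(theta)))
    return MomentArmProfile(muscle=muscle.name, joint=joint, mode="isolated",
                            samples=samples, sweep_joint=swept)


def stepping_profile(chain: KinematicChain, muscle: MusclePath, joint: str,
                     trajectories: dict[str, GaitTrajectory],
                     n_samples: int = 100) -> MomentArmProfile:
    """Moment arm over a physiological stride, sampled uniformly in time.

    Samples at t = k / n_samples for k = 0 .. n_samples-1; each sample
    records every joint angle, since the arm of a biarticular muscle
    depends on both spanned joints.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    segment = free_segment(muscle, chain, joint)
    samples = []
    for k in range(n_samples):
        t = k / n_samples
        pose = pose_at(chain, trajectories, t)
        r = moment_arm(muscle, pose, chain, joint, segment=segment)
        samples.append(MomentArmSample(muscle=muscle.name, joint=joint, r=r,
                                       angles=dict(pose.joint_angles), t=t))
    return MomentArmProfile(muscle=muscle.name, joint=joint, mode="stepping",
                            samples=samples)


def moment_arm_vs_length(chain: KinematicChain, muscle: MusclePath, joint: str,
                         trajectories: dict[str, GaitTrajectory],
                         n_samples: int = 100, normalize: bool = True,
                         phase: StridePhase | None = None) -> MomentArmLengthLoop:
    """Moment arm against muscle-tendon length over one stride.

    Both quantities are min-max normalised over the cycle unless
    ``normalize=False``.  A constant-length muscle (zero length range)
    cannot be min-max normalised; its raw length is returned with
    ``constant_length=True`` instead of dividing by a zero range.
    """
    profile = stepping_profile(chain, muscle, joint, trajectories, n_samples)
    t = profile.abscissa
    r = profile.r
    lengths = np.array([
        muscle_length(muscle, pose_at(chain, trajectories, tk)) for tk in t])

    constant = False
    if normalize:
        l_range = lengths.max() - lengths.min()
        r_range = r.max() - r.min()
        if l_range < 1e-12:
            constant = True  # leave lengths raw rather than divide by ~0
        else:
            lengths = (lengths - lengths.min()) / l_range
        if r_range >= 1e-12:
            r = (r - r.min()) / r_range
    return MomentArmLengthLoop(muscle=muscle.name, joint=joint, t=t,
                               length=lengths, r=r, normalized=normalize,
                               constant_length=constant, phase=phase)


def _perturbed_muscle(muscle: MusclePath, spec: PerturbationSpec,
                      sign: float) -> MusclePath:
    clone = copy.deepcopy(muscle)
    att = clone.attachments[spec.attachment_index]
    att.local_position = att.local_position + sign * spec.magnitude * spec.direction
    return clone


def sensitivity_analysis(chain: KinematicChain, muscle: MusclePath, joint: str,
                         spec: PerturbationSpec,
                         sweep: tuple[float, float, float],
                         fixed_angles: dict[str, float] | None = None,
                         sweep_joint: str | None = None) -> SensitivityResult:
    """Baseline vs +/- perturbed isolated profiles for one attachment.

    The perturbation displaces one end of the free segment by
    ``spec.magnitude`` mm along ``spec.direction`` in that attachment's
    body-local frame, once in each direction, and recomputes the profile
    on the identical sweep.
    """
    if spec.muscle != muscle.name:
        raise ValueError(
            f"perturbation spec addresses muscle '{spec.muscle}', got '{muscle.name}'")
    segment = free_segment(muscle, chain, joint)
    if spec.attachment_index not in (segment.proximal_index, segment.distal_index):
        raise ValueError(
            f"attachment index {spec.attachment_index} is not an end of the free "
            f"segment ({segment.proximal_index}, {segment.distal_index}) of "
            f"'{muscle.name}' about '{joint}'")

    baseline = isolated_joint_profile(chain, muscle, joint, sweep,
                                      fixed_angles, sweep_joint)
    plus = isolated_joint_profile(chain, _perturbed_muscle(muscle, spec, +1.0),
                                  joint, sweep, fixed_angles, sweep_joint)
    minus = isolated_joint_profile(chain, _perturbed_muscle(muscle, spec, -1.0),
                                   joint, sweep, fixed_angles, sweep_joint)
    dev = max(float(np.max(np.abs(plus.r - baseline.r))),
              float(np.max(np.abs(minus.r - baseline.r))))
    return SensitivityResult(spec=spec, baseline=baseline, perturbed_plus=plus,
                             perturbed_minus=minus, max_abs_deviation=dev)


def normalize_profile(profile: MomentArmProfile, femur_length: float) -> MomentArmProfile:
    """Divide every moment arm by a reference (femur) length in mm.

    Femur-length scaling puts models of different body size on a common
    dimensionless axis.  Normalising twice is refused.
    """
    if femur_length <= 0:
        raise ValueError(f"femur_length must be > 0, got {femur_length}")
    if profile.normalization != "none":
        raise ValueError("profile is already normalized")
    samples = [
        MomentArmSample(muscle=s.muscle, joint=s.joint, r=s.r / femur_length,
                        angles=dict(s.angles), theta_deg=s.theta_deg, t=s.t)
        for s in profile.samples]
    return MomentArmProfile(muscle=profile.muscle, joint=profile.joint,
                            mode=profile.mode, samples=samples,
                            normalization="femur_length",
                            reference_length=float(femur_length),
                            sweep_joint=profile.sweep_joint)


def reachable_surface(chain: KinematicChain, muscle: MusclePath,
                      profile: MomentArmProfile, resolution: float = 1.0,
                      mask_distance_cells: float = 2.0) -> SurfaceGrid:
    """Moment arm of a biarticular muscle on a (theta1, theta2) grid.

    The grid spans the axis-aligned bounding box of the spanned-joint
    angle pairs visited by the stepping profile, at ``resolution`` degrees
    per cell, and is masked to cells within ``mask_distance_cells`` cells
    of the visited trajectory.  Grid poses hold all non-spanned joints at
    zero; the arm about a single-free-segment muscle does not depend on
    them, so grid values coincide with stepping samples at coincident
    angles.
    """
    joints = spanned_joints(muscle, chain)
    if len(joints) != 2:
        raise ValueError(
            f"reachable_surface needs a biarticular muscle; '{muscle.name}' "
            f"spans {len(joints)} joint(s)")
    if profile.mode != "stepping":
        raise ValueError("reachable_surface needs a stepping profile")
    j1, j2 = joints
    segment = free_segment(muscle, chain, profile.joint)

    visited = np.array([[s.angles[j1], s.angles[j2]] for s in profile.samples])

    def axis_values(lo: float, hi: float) -> np.ndarray:
        if hi - lo < 1e-12:
            return np.array([lo])
        n = int(math.ceil((hi - lo) / resolution))
        return np.linspace(lo, lo + n * resolution, n + 1)

    theta1 = axis_values(visited[:, 0].min(), visited[:, 0].max())
    theta2 = axis_values(visited[:, 1].min(), visited[:, 1].max())

    g1, g2 = np.meshgrid(theta1, theta2, indexing="ij")
    # distance (in cells) from each node to the nearest visited angle pair
    d1 = (g1[..., None] - visited[None, None, :, 0]) / resolution
    d2 = (g2[..., None] - visited[None, None, :, 1]) / resolution
    dist = np.sqrt(d1 ** 2 + d2 ** 2).min(axis=-1)
    mask = dist <= mask_distance_cells

    r = np.full(g1.shape, np.nan)
    base = {name: 0.0 for name in chain.joint_names()}
    for i in range(g1.shape[0]):
        for k in range(g1.shape[1]):
            if not mask[i, k]:
                continue
            angles = dict(base)
            angles[j1] = float(g1[i, k])
            angles[j2] = float(g2[i, k])
            pose = forward_kinematics(chain, angles, ignore_limits=True)
            r[i, k] = moment_arm(muscle, pose, chain, profile.joint, segment=segment)
    return SurfaceGrid(muscle=muscle.name, joint=profile.joint,
                       joint_pair=(j1, j2), theta1=theta1, theta2=theta2,
                       r=r, mask=mask)
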