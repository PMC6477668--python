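"""Periodic sum-of-sines joint-angle trajectories over a normalised stride.

Joint-angle profiles digitised from walking recordings are represented as

    theta(t) = offset + sum_k a_k * sin(b_k * t + c_k)

with stride time t in [0, 1): touch down at t = 0, lift off somewhere in
(0, 1) separating stance from swing.  In the default *periodic* mode the
angular frequencies are fixed at harmonics of the stride, b_k = 2*pi*k, so
the fitted curve closes exactly into a loop; a free-frequency mode is
available for fidelity to arbitrary fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .core import KinematicChain, Pose, forward_kinematics

__all__ = [
    "GaitTrajectory",
    "StridePhase",
    "fit_sum_of_sines",
    "eval_trajectory",
    "pose_at",
]


@dataclass
class GaitTrajectory:
    """Sum-of-sines model of one joint's angle over a normalised stride.

    ``terms`` is a list of (amplitude a_k in degrees, angular frequency
    b_k in radians per stride, phase c_k in radians).  ``rmse`` carries
    the fit residual when the trajectory came from :func:`fit_sum_of_sines`.
    """

    joint: str
    offset: float
    terms: list[tuple[float, float, float]]
    periodic: bool = True
    rmse: float | None = None

    def __post_init__(self) -> None:
        if len(self.terms) < 1:
            raise ValueError("trajectory needs at least one sine term")
        self.terms = [(float(a), float(b), float(c)) for a, b, c in self.terms]

    def __call__(self, t):
        """Angle in degrees at stride time t (scalar or array)."""
        t = np.asarray(t, dtype=float)
        out = np.full_like(t, self.offset, dtype=float)
        for a, b, c in self.terms:
            out = out + a * np.sin(b * t + c)
        return float(out) if out.ndim == 0 else out


@dataclass
class StridePhase:
    """Stride event markers in normalised time: touch down and lift off."""

    touch_down: float = 0.0
    lift_off: float = 0.6

    def __post_init__(self) -> None:
        if not 0.0 <= self.touch_down < self.lift_off < 1.0:
            raise ValueError(
                f"need 0 <= touch_down < lift_off < 1, got "
                f"({self.touch_down}, {self.lift_off})")


def _periodic_lstsq(t: np.ndarray, y: np.ndarray, n_terms: int):
    """Linear least squares on the harmonic basis 1, sin(2*pi*k*t), cos(2*pi*k*t)."""
    cols = [np.ones_like(t)]
    for k in range(1, n_terms + 1):
        cols.append(np.sin(2 * np.pi * k * t))
        cols.append(np.cos(2 * np.pi * k * t))
    design = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return coef, resid


def fit_sum_of_sines(samples, n_terms: int = 4, periodic: bool = True,
                     joint: str = "") -> GaitTrajectory:
    """Fit theta(t) = offset + sum a_k sin(b_k t + c_k) to (t, angle) samples.

    Parameters
    ----------
    samples
        Sequence of (t, angle_deg) pairs, or an (n, 2) array, with t in
        [0, 1).
    n_terms
        Number of sine terms (default 4, typical for smooth gait curves).
    periodic
        Fix b_k = 2*pi*k (harmonics of the stride) and solve the then
        linear problem exactly; when False the frequencies are refined by
        nonlinear least squares initialised from the harmonic solution.
    joint
        Joint name recorded on the returned trajectory.

    Returns a :class:`GaitTrajectory` with its ``rmse`` field set.
    """
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("samples must be an (n, 2) array of (t, angle) pairs")
    t, y = arr[:, 0], arr[:, 1]
    n_min = 2 * (2 * n_terms + 1)
    if len(t) < n_min:
        raise ValueError(
            f"need at least {n_min} samples for n_terms={n_terms}, got {len(t)}")
    if np.any((t < 0) | (t >= 1)):
        raise ValueError("sample times must lie in [0, 1)")

    coef, resid = _periodic_lstsq(t, y, n_terms)
    offset = float(coef[0])
    terms: list[tuple[float, float, float]] = []
    for k in range(1, n_terms + 1):
        a_sin, a_cos = coef[2 * k - 1], coef[2 * k]
        amp = math.hypot(a_sin, a_cos)
        phase = math.atan2(a_cos, a_sin)  # a sin(bt+c) = a sin(bt) cos c + a cos(bt) sin c
        terms.append((amp, 2 * math.pi * k, phase))

    if periodic:
        rmse = float(np.sqrt(np.mean(resid ** 2)))
        return GaitTrajectory(joint=joint, offset=offset, terms=terms,
                              periodic=True, rmse=rmse)

    # free-frequency refinement, deterministically initialised from the
    # harmonic (DFT-equivalent) solution
    p0 = [offset]
    for a, b, c in terms:
        p0.extend([a, b, c])

    def residuals(p):
        model = np.full_like(t, p[0])
        for k in range(n_terms):
            a, b, c = p[1 + 3 * k: 4 + 3 * k]
            model = model + a * np.sin(b * t + c)
        return model - y

    res = least_squares(residuals, p0, method="lm", max_nfev=20000)
    if not res.success:
        raise RuntimeError(
            f"sum-of-sines fit did not converge: {res.message}; "
            f"final residual norm {np.linalg.norm(res.fun):.3g}")
    p = res.x
    terms = [(float(p[1 + 3 * k]), float(p[2 + 3 * k]), float(p[3 + 3 * k]))
             for k in range(n_terms)]
    rmse = float(np.sqrt(np.mean(res.fun ** 2)))
    return GaitTrajectory(joint=joint, offset=float(p[0]), terms=terms,
                          periodic=False, rmse=rmse)


def eval_trajectory(traj: GaitTrajectory, t) -> float | np.ndarray:
    """Angle (degrees) at stride time ``t``; periodic trajectories wrap."""
    return traj(t)


def pose_at(chain: KinematicChain, trajectories: dict[str, GaitTrajectory],
            t: float, *, ignore_limits: bool = False) -> Pose:
    """Forward kinematics at stride time ``t`` from per-joint trajectories."""
    missing = sorted(set(chain.joint_names()) - set(trajectories))
    if missing:
        raise ValueError(f"missing trajectory for joint(s) {missing}")
    angles = {name: float(trajectories[name](t)) for name in chain.joint_names()}
    return forward_kinematics(chain, angles, ignore_limits=ignore_limits)
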