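"""Planar two-link arm model: gravity compensation, weight estimation, torques.

The exoskeleton-supported arm is reduced to a planar two-link chain in the
task's vertical (y, z) plane: shoulder elevation and elbow flexion.  Angles
are measured from the downward vertical (0 = segment hanging straight down,
positive toward +y); the elbow angle is relative to the upper-arm segment.

The weight-support controller cancels a configurable fraction of the static
gravity torques at every pose, so supported participants need no holding
torque.  Per-participant segment masses are identified from static torque
readings at a calibration pose; the static model is linear in the two masses,
so ordinary least squares applies.

Unlike the virtual pendulum (which lives under reduced gravity), the arm is
under full earth gravity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import EstimationError
from .pendulum import EARTH_GRAVITY

__all__ = [
    "ArmParams",
    "ArmPose",
    "JointTorques",
    "ArmWeightEstimate",
    "gravity_torques",
    "weight_support_torques",
    "estimate_arm_weights",
    "hand_force_to_joint_torques",
    "generated_torques",
    "jacobian",
    "hand_position",
    "inverse_kinematics",
]


@dataclass(frozen=True)
class ArmParams:
    """Segment masses (kg), lengths (m), and COM fractions of the two links."""

    m_upper: float = 2.0
    m_lower: float = 1.5
    l_upper: float = 0.30
    l_lower: float = 0.25
    r_upper: float = 0.5
    r_lower: float = 0.5

    def __post_init__(self) -> None:
        if self.m_upper < 0 or self.m_lower < 0:
            raise ValueError("segment masses must be non-negative")
        if self.l_upper <= 0 or self.l_lower <= 0:
            raise ValueError("segment lengths must be positive")
        if not (0 < self.r_upper < 1 and 0 < self.r_lower < 1):
            raise ValueError("COM fractions must lie in (0, 1)")


@dataclass(frozen=True)
class ArmPose:
    """Planar arm pose: shoulder elevation and elbow flexion (rad)."""

    q_shoulder: float
    q_elbow: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.q_shoulder) and math.isfinite(self.q_elbow)):
            raise ValueError("pose angles must be finite")


#: Planar reduction of the calibration pose used for weight estimation
#: (-10 deg shoulder elevation, -30 deg elbow flexion).
CALIBRATION_POSE = ArmPose(q_shoulder=math.radians(-10.0),
                           q_elbow=math.radians(-30.0))


@dataclass(frozen=True)
class JointTorques:
    """Joint torque vector ordered (shoulder, elbow), N*m."""

    tau: tuple

    def __post_init__(self) -> None:
        tau = tuple(float(x) for x in self.tau)
        if not all(math.isfinite(x) for x in tau):
            raise ValueError("torques must be finite")
        object.__setattr__(self, "tau", tau)

    @property
    def shoulder(self) -> float:
        return self.tau[0]

    @property
    def elbow(self) -> float:
        return self.tau[1]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.tau, dtype=float)

    def __add__(self, other: "JointTorques") -> "JointTorques":
        return JointTorques(tuple(a + b for a, b in zip(self.tau, other.tau)))


def _pose_arrays(pose):
    """Accept an ArmPose or arrays (q_shoulder, q_elbow); return arrays."""
    if isinstance(pose, ArmPose):
        return np.asarray(pose.q_shoulder), np.asarray(pose.q_elbow)
    q_s, q_e = pose
    return np.asarray(q_s, dtype=float), np.asarray(q_e, dtype=float)


def _gravity_tau(q_s, q_e, arm: ArmParams, g: float):
    s1 = np.sin(q_s)
    s12 = np.sin(q_s + q_e)
    tau_elbow = g * arm.m_lower * arm.r_lower * arm.l_lower * s12
    tau_shoulder = g * (
        arm.m_upper * arm.r_upper * arm.l_upper * s1
        + arm.m_lower * (arm.l_upper * s1 + arm.r_lower * arm.l_lower * s12)
    )
    return tau_shoulder, tau_elbow


def gravity_torques(pose, arm: ArmParams, g_earth: float = EARTH_GRAVITY):
    """Static joint torques needed to hold the arm against gravity.

    Positive torque = torque the participant must generate.  For an
    :class:`ArmPose` a :class:`JointTorques` is returned; array poses yield
    an (n, 2) array.
    """
    q_s, q_e = _pose_arrays(pose)
    tau_s, tau_e = _gravity_tau(q_s, q_e, arm, g_earth)
    if np.ndim(tau_s) == 0:
        return JointTorques((float(tau_s), float(tau_e)))
    return np.stack([tau_s, tau_e], axis=-1)


def weight_support_torques(pose, arm: ArmParams, support_fraction: float,
                           g_earth: float = EARTH_GRAVITY):
    """Robot support torques cancelling ``support_fraction`` of gravity.

    At ``support_fraction = 1`` the supported arm requires zero net holding
    torque at any pose.
    """
    if not 0.0 <= support_fraction <= 1.0:
        raise ValueError("support_fraction must lie in [0, 1]")
    tau = gravity_torques(pose, arm, g_earth)
    if isinstance(tau, JointTorques):
        return JointTorques(tuple(-support_fraction * x for x in tau.tau))
    return -support_fraction * tau


def hand_position(pose, arm: ArmParams):
    """Hand (y, z) position relative to the shoulder."""
    q_s, q_e = _pose_arrays(pose)
    y = arm.l_upper * np.sin(q_s) + arm.l_lower * np.sin(q_s + q_e)
    z = -arm.l_upper * np.cos(q_s) - arm.l_lower * np.cos(q_s + q_e)
    return y, z


def jacobian(pose, arm: ArmParams) -> np.ndarray:
    """Planar positional Jacobian d(y, z)/d(q_shoulder, q_elbow) (2x2)."""
    q_s, q_e = _pose_arrays(pose)
    c1, c12 = np.cos(q_s), np.cos(q_s + q_e)
    s1, s12 = np.sin(q_s), np.sin(q_s + q_e)
    return np.array([
        [arm.l_upper * c1 + arm.l_lower * c12, arm.l_lower * c12],
        [arm.l_upper * s1 + arm.l_lower * s12, arm.l_lower * s12],
    ])


def hand_force_to_joint_torques(f_hand, pose, arm: ArmParams):
    """Map a hand force (F_y, F_z) to joint torques via tau = J^T F."""
    if isinstance(pose, ArmPose):
        tau = jacobian(pose, arm).T @ np.asarray(f_hand, dtype=float)
        return JointTorques((float(tau[0]), float(tau[1])))
    # vectorised: pose = (q_s array, q_e array), f_hand = (F_y array, F_z array)
    q_s, q_e = _pose_arrays(pose)
    f_y = np.asarray(f_hand[0], dtype=float)
    f_z = np.asarray(f_hand[1], dtype=float)
    c1, c12 = np.cos(q_s), np.cos(q_s + q_e)
    s1, s12 = np.sin(q_s), np.sin(q_s + q_e)
    tau_s = (arm.l_upper * c1 + arm.l_lower * c12) * f_y + (
        arm.l_upper * s1 + arm.l_lower * s12) * f_z
    tau_e = arm.l_lower * c12 * f_y + arm.l_lower * s12 * f_z
    return np.stack([tau_s, tau_e], axis=-1)


def inverse_kinematics(y, z, arm: ArmParams, eps: float = 1e-6):
    """Elbow-down inverse kinematics of the planar arm, reach-clamped.

    Targets outside the annulus of reachable radii are radially clamped, so
    the map is total (needed when a clipped pivot trajectory is converted to
    poses).  Returns arrays (q_shoulder, q_elbow).
    """
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    r = np.hypot(y, z)
    r_min = abs(arm.l_upper - arm.l_lower) + eps
    r_max = arm.l_upper + arm.l_lower - eps
    r_clamped = np.clip(r, r_min, r_max)
    scale = np.where(r > 0, r_clamped / np.maximum(r, eps), 1.0)
    y, z = y * scale, z * scale
    cos_q_e = (r_clamped**2 - arm.l_upper**2 - arm.l_lower**2) / (
        2.0 * arm.l_upper * arm.l_lower)
    q_e = np.arccos(np.clip(cos_q_e, -1.0, 1.0))
    # angle of the target from the downward vertical
    phi = np.arctan2(y, -z)
    psi = np.arctan2(arm.l_lower * np.sin(q_e),
                     arm.l_upper + arm.l_lower * np.cos(q_e))
    q_s = phi - psi
    return q_s, q_e


@dataclass(frozen=True)
class ArmWeightEstimate:
    """Least-squares segment-mass estimate from static calibration torques."""

    m_upper: float
    m_lower: float
    residual: float
    in_physical_range: bool


def estimate_arm_weights(static_readings, arm_geometry: ArmParams,
                         pose: ArmPose = CALIBRATION_POSE,
                         g_earth: float = EARTH_GRAVITY) -> ArmWeightEstimate:
    """Estimate the two segment masses from static torque readings.

    ``static_readings`` is an (n, 2) array of (shoulder, elbow) torque
    samples recorded while the arm holds ``pose`` (e.g. 10 s at 100 Hz).
    The static gravity model is linear in the masses,

        tau = g * M(q) @ (m_upper, m_lower),

    and is solved by least squares over all samples.  The COM fractions and
    lengths of ``arm_geometry`` are taken as known; its masses are ignored.
    """
    readings = np.atleast_2d(np.asarray(static_readings, dtype=float))
    if readings.shape[1] != 2 or readings.shape[0] < 1:
        raise ValueError("static_readings must be an (n, 2) torque array")
    s1 = math.sin(pose.q_shoulder)
    s12 = math.sin(pose.q_shoulder + pose.q_elbow)
    geom = arm_geometry
    design = g_earth * np.array([
        [geom.r_upper * geom.l_upper * s1,
         geom.l_upper * s1 + geom.r_lower * geom.l_lower * s12],
        [0.0, geom.r_lower * geom.l_lower * s12],
    ])
    if np.linalg.matrix_rank(design, tol=1e-10) < 2:
        raise EstimationError(
            "calibration pose makes the two mass columns collinear")
    # stack the 2x2 model once per sample
    n = readings.shape[0]
    big_design = np.tile(design, (n, 1))
    rhs = readings.reshape(-1)
    sol, res, _, _ = np.linalg.lstsq(big_design, rhs, rcond=None)
    residual = float(np.sqrt(res[0] / rhs.size)) if res.size else 0.0
    m_upper, m_lower = float(sol[0]), float(sol[1])
    return ArmWeightEstimate(
        m_upper=m_upper,
        m_lower=m_lower,
        residual=residual,
        in_physical_range=(m_upper > 0.0 and m_lower > 0.0),
    )


def generated_torques(interaction, poses, arm: ArmParams,
                      g_earth: float = EARTH_GRAVITY):
    """Participant-generated torques: interaction + static holding torques.

    ``interaction`` is an (n, 2) series of measured interaction torques and
    ``poses`` a matching pose series ((q_s, q_e) arrays or list of
    :class:`ArmPose`).  Returns an (n, 2) array.
    """
    interaction = np.atleast_2d(np.asarray(interaction, dtype=float))
    if isinstance(poses, tuple) and len(poses) == 2:
        q_s, q_e = _pose_arrays(poses)
    else:
        poses = list(poses)
        q_s = np.array([p.q_shoulder for p in poses])
        q_e = np.array([p.q_elbow for p in poses])
    if interaction.shape[0] != q_s.size:
        raise ValueError("interaction and pose series lengths differ")
    hold = gravity_torques((q_s, q_e), arm, g_earth)
    hold = np.atleast_2d(hold)
    return interaction + hold
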