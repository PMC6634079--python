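"""Pelvic reference frame, cup orientation and femoral kinematics.

Frame convention (right hip): right-handed pelvic frame with X lateral
(operative side), Y anterior, Z superior.  The hip centre of rotation is at
the origin; the femoral head centre coincides with it in every pose.  Left
hips are handled by mirroring anteversions at the input boundary, never by a
second code path.

Cup orientation uses Murray's *radiographic* definitions: inclination is the
angle of the coronal-plane projection of the cup axis from the longitudinal
axis, anteversion the elevation of the cup axis out of the coronal plane.

Femoral motion is composed in a fixed order: the neck-shaft angle is part of
the stem geometry, then the fixed pose rotations (stem flexion, adduction,
then stem anteversion about the shaft axis), then the primary motion
(flexion/extension about the pelvic medio-lateral axis) and finally the
secondary motion (internal/external rotation about the current femoral shaft
axis).  Everything is done with rotation matrices / quaternions; Euler angles
are never extracted mid-pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

X_LATERAL = np.array([1.0, 0.0, 0.0])
Y_ANTERIOR = np.array([0.0, 1.0, 0.0])
Z_SUPERIOR = np.array([0.0, 0.0, 1.0])

#: shaft axis of the femur in the neutral stem frame (pointing proximally)
SHAFT_AXIS = Z_SUPERIOR

PRIMARY_KINDS = ("flexion", "extension")
SECONDARY_KINDS = ("internal_rotation", "external_rotation")


@dataclass(frozen=True)
class CupOrientation:
    """Radiographic cup inclination/anteversion in degrees."""

    inclination_deg: float
    anteversion_deg: float

    def axis(self) -> np.ndarray:
        return cup_axis(self.inclination_deg, self.anteversion_deg)


@dataclass(frozen=True)
class StemPose:
    """Fixed placement of the femoral component.

    ``anteversion_deg`` rotates the femur about its shaft axis so that the
    neck gains an anterior component for positive values; adduction (default
    6 deg, the natural standing adduction of the femur) tilts the shaft
    medially about the anterior axis; stem flexion (default 0) tilts it about
    the medio-lateral axis.
    """

    anteversion_deg: float = 0.0
    adduction_deg: float = 6.0
    flexion_deg: float = 0.0


@dataclass(frozen=True)
class JointMotion:
    """A combined motion: primary (flexion/extension) then secondary
    (internal/external rotation), both in degrees, applied in that order."""

    primary: str = "flexion"
    primary_deg: float = 0.0
    secondary: str = "internal_rotation"
    secondary_deg: float = 0.0

    def __post_init__(self):
        if self.primary not in PRIMARY_KINDS:
            raise ValueError(f"unknown primary motion {self.primary!r}")
        if self.secondary not in SECONDARY_KINDS:
            raise ValueError(f"unknown secondary motion {self.secondary!r}")
        if self.primary_deg < 0 or self.secondary_deg < 0:
            raise ValueError("motion angles must be >= 0")


def cup_axis(inclination_deg: float, anteversion_deg: float) -> np.ndarray:
    """Outward cup-face normal for radiographic (Murray) angles.

    u = (sin a * cos b, sin b, -cos a * cos b) with a = inclination,
    b = anteversion: at (0, 0) the cup opens straight inferiorly, at (90, 0)
    straight laterally, positive anteversion tips the opening anteriorly.
    """
    a = np.radians(inclination_deg)
    b = np.radians(anteversion_deg)
    return np.array(
        [np.sin(a) * np.cos(b), np.sin(b), -np.cos(a) * np.cos(b)]
    )


def cup_axis_grid(inclination_deg, anteversion_deg) -> np.ndarray:
    """Vectorised :func:`cup_axis`; broadcasts to an (..., 3) array."""
    a = np.radians(np.asarray(inclination_deg, dtype=float))
    b = np.radians(np.asarray(anteversion_deg, dtype=float))
    a, b = np.broadcast_arrays(a, b)
    return np.stack(
        [np.sin(a) * np.cos(b), np.sin(b), -np.cos(a) * np.cos(b)], axis=-1
    )


def cup_angles(axis: np.ndarray) -> tuple[float, float]:
    """Inverse of :func:`cup_axis` (degrees)."""
    u = np.asarray(axis, dtype=float)
    u = u / np.linalg.norm(u)
    beta = np.degrees(np.arcsin(np.clip(u[1], -1.0, 1.0)))
    alpha = np.degrees(np.arctan2(u[0], -u[2]))
    return float(alpha), float(beta)


def _rot(axis: np.ndarray, angle_deg: float) -> Rotation:
    return Rotation.from_rotvec(np.radians(angle_deg) * np.asarray(axis))


def pose_rotation(pose: StemPose) -> Rotation:
    """Rotation taking the neutral stem frame into the pelvic frame.

    Order: stem flexion (about X), adduction (about Y, distal femur moving
    medially for positive angles), then anteversion about the resulting shaft
    axis (neck moving anteriorly for positive angles).
    """
    r = _rot(Y_ANTERIOR, pose.adduction_deg) * _rot(X_LATERAL, pose.flexion_deg)
    shaft = r.apply(SHAFT_AXIS)
    return _rot(shaft, -pose.anteversion_deg) * r


def primary_rotation(kind: str, angle_deg: float) -> Rotation:
    sign = 1.0 if kind == "flexion" else -1.0
    return _rot(X_LATERAL, sign * angle_deg)


def secondary_sign(kind: str) -> float:
    """Sign of the rotation about the proximally-pointing shaft axis."""
    return 1.0 if kind == "internal_rotation" else -1.0


def motion_rotation(pose: StemPose, motion: JointMotion) -> Rotation:
    """Full rotation stem frame -> pelvic frame for a pose plus motion."""
    rp = primary_rotation(motion.primary, motion.primary_deg) * pose_rotation(pose)
    shaft = rp.apply(SHAFT_AXIS)
    rs = _rot(shaft, secondary_sign(motion.secondary) * motion.secondary_deg)
    return rs * rp


def stem_neck_axis(pose: StemPose, neck_axis_stem, motion: JointMotion) -> np.ndarray:
    """Neck axis (unit vector, toward the head) in the pelvic frame."""
    return motion_rotation(pose, motion).apply(np.asarray(neck_axis_stem))


def _angle_steps(total_deg: float, step_deg: float) -> np.ndarray:
    """0 .. total inclusive with uniform spacing <= step."""
    if total_deg <= 0:
        return np.array([0.0])
    n = max(1, int(np.ceil(total_deg / step_deg)))
    return np.linspace(0.0, total_deg, n + 1)


@dataclass
class MotionPath:
    """Discretised primary-then-secondary motion as rotation matrices.

    ``matrices[i]`` maps stem-frame points into the pelvic frame at path
    station i.  Stations 0..n_primary-1 sweep the primary motion from 0 to
    its full angle; the remainder sweep the secondary rotation with the
    primary held at its end value.  ``secondary_matrix(theta)`` gives the
    rotation at an arbitrary secondary angle for bisection refinement.
    """

    matrices: np.ndarray
    primary_angles: np.ndarray
    secondary_angles: np.ndarray
    _r_primary_end: Rotation = field(repr=False)
    _shaft_axis: np.ndarray = field(repr=False)
    _secondary_sign: float = field(repr=False)
    _primary_base: Rotation = field(repr=False)
    _primary_kind: str = field(repr=False)

    @property
    def n_primary(self) -> int:
        return len(self.primary_angles)

    def primary_matrix(self, angle_deg: float) -> np.ndarray:
        r = primary_rotation(self._primary_kind, angle_deg) * self._primary_base
        return r.as_matrix()

    def secondary_matrix(self, angle_deg: float) -> np.ndarray:
        r = _rot(self._shaft_axis, self._secondary_sign * angle_deg)
        return (r * self._r_primary_end).as_matrix()


def motion_path(
    pose: StemPose, motion: JointMotion, step_deg: float = 2.0
) -> MotionPath:
    """Discretise a primary-then-secondary motion from the neutral pose."""
    base = pose_rotation(pose)
    p_angles = _angle_steps(motion.primary_deg, step_deg)
    sign_p = 1.0 if motion.primary == "flexion" else -1.0
    rp = Rotation.from_rotvec(
        np.radians(sign_p * p_angles)[:, None] * X_LATERAL[None, :]
    )
    prim_mats = rp.as_matrix() @ base.as_matrix()

    r_primary_end = rp[-1] * base
    shaft = r_primary_end.apply(SHAFT_AXIS)
    sign_s = secondary_sign(motion.secondary)
    s_angles = _angle_steps(motion.secondary_deg, step_deg)[1:]
    if len(s_angles):
        rs = Rotation.from_rotvec(
            np.radians(sign_s * s_angles)[:, None] * shaft[None, :]
        )
        sec_mats = rs.as_matrix() @ r_primary_end.as_matrix()
        mats = np.concatenate([prim_mats, sec_mats], axis=0)
    else:
        mats = prim_mats
    return MotionPath(
        matrices=mats,
        primary_angles=p_angles,
        secondary_angles=s_angles,
        _r_primary_end=r_primary_end,
        _shaft_axis=shaft,
        _secondary_sign=sign_s,
        _primary_base=base,
        _primary_kind=motion.primary,
    )
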