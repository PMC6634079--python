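"""Analytical cone-overlap range-of-motion model and boundary solving.

The liner rim circle lies on the cavity sphere of radius r at polar angle
phi from the cup axis, with cos(phi) = (d - r) / r for a cavity of depth d
(phi = 90 deg for a hemispherical liner, larger for shallow liners whose rim
sits past the equator, smaller for lipped ones).  A neck of width n at the
impingement level subtends a half-angle gamma at the head centre with
sin(gamma) = n / (2 r).  The prosthesis is impingement-free exactly while
the (distal) neck axis stays within phi - gamma of the outward cup-face
normal; the maximum secondary rotation at a given primary angle is the first
crossing of that cone, which has a closed form because the neck axis traces
a circular cone about the femoral shaft axis during axial rotation.

Boundary solving finds, per cup inclination, the cup anteversion at which
the achieved secondary rotation equals a user-defined target (e.g. 30 deg IR
at 90 deg flexion anteriorly, 10 deg ER at 10 deg extension posteriorly).
Neck width is supplied per cup/stem orientation by the neck-width database
(or a constant for cylindrical necks, for which the formula is exact).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .implants import HeadSpec, LinerSpec
from .kinematics import (
    SHAFT_AXIS,
    CupOrientation,
    JointMotion,
    StemPose,
    cup_axis_grid,
    motion_path,
    secondary_sign,
)
from .neckwidth import (
    EXTENSION_SIDE,
    FLEXION_SIDE,
    SIDE_MOTIONS,
    NeckWidthDatabase,
)

__all__ = [
    "ROMTarget",
    "GeometricInfeasibilityError",
    "cone_half_angles",
    "max_secondary_rotation",
    "achieved_rom",
    "ImpingementBoundary",
    "solve_boundary",
    "solve_boundary_alpha",
]

#: "never impinges" sentinel for the secondary rotation, degrees
SENTINEL_DEG = 170.0


class GeometricInfeasibilityError(ValueError):
    """Neck wider than the cup opening: gamma >= phi, no motion possible."""


@dataclass(frozen=True)
class ROMTarget:
    """Combined target ROM: IR at flexion (anterior test) and ER at
    extension (posterior test), all angles in degrees and >= 0."""

    ir_deg: float
    fl_deg: float
    er_deg: float
    ex_deg: float

    def __post_init__(self):
        if min(self.ir_deg, self.fl_deg, self.er_deg, self.ex_deg) < 0:
            raise ValueError("ROM target angles must be >= 0")

    def motion(self, side: str) -> JointMotion:
        pk, sk = SIDE_MOTIONS[side]
        if side == FLEXION_SIDE:
            return JointMotion(pk, self.fl_deg, sk, self.ir_deg)
        return JointMotion(pk, self.ex_deg, sk, self.er_deg)

    def secondary_target(self, side: str) -> float:
        return self.ir_deg if side == FLEXION_SIDE else self.er_deg

    def __str__(self):
        return (
            f"{self.ir_deg:g}IR@{self.fl_deg:g}FL,"
            f"{self.er_deg:g}ER@{self.ex_deg:g}EX"
        )


def cone_half_angles(head: HeadSpec, liner: LinerSpec,
                     neck_width_mm) -> tuple[float, np.ndarray]:
    """(phi, gamma) in degrees: rim polar angle and neck half-angle.

    phi is the polar angle of the rim circle measured from the outward cup
    axis: cos(phi) = (d - r) / r, so phi = 90 deg for a hemispherical liner,
    more for a shallow liner (rim past the equator, more clearance) and less
    for a lipped one.  sin(gamma) = n / (2 r).  Raises
    :class:`GeometricInfeasibilityError` when gamma >= phi anywhere.
    """
    r = head.radius_mm
    d = liner.depth_mm
    n = np.asarray(neck_width_mm, dtype=float)
    if np.any(n <= 0) or np.any(n > 2 * r):
        raise ValueError("neck width must satisfy 0 < n <= 2r")
    phi = float(np.degrees(np.arccos(np.clip((d - r) / r, -1.0, 1.0))))
    gamma = np.degrees(np.arcsin(n / (2.0 * r)))
    if np.any(gamma >= phi):
        raise GeometricInfeasibilityError(
            f"neck half-angle gamma >= rim polar angle phi ({phi:.2f} deg): "
            "the neck cannot clear the cup opening"
        )
    return phi, gamma


def _first_cone_exit(U: np.ndarray, cos_limit: np.ndarray, m_end: np.ndarray,
                     shaft: np.ndarray, sign: float,
                     cap_deg: float = SENTINEL_DEG) -> np.ndarray:
    """Smallest secondary angle (deg) at which angle(m, u) reaches the limit.

    During axial rotation by theta about k = sign * shaft the dot product is
    m(theta).u = K + A cos(theta) + B sin(theta) with K = (k.m)(k.u); the
    first crossing of cos_limit is closed-form.  Returns 0 where the end of
    the primary motion already violates the cone and ``cap_deg`` where the
    cone is never exited.
    """
    U = np.atleast_2d(U)
    cos_limit = np.broadcast_to(np.asarray(cos_limit, float), (len(U),))
    k = sign * shaft
    km = float(np.dot(k, m_end))
    K = km * (U @ k)
    A = U @ m_end - K
    B = U @ np.cross(k, m_end)
    f0 = K + A  # = m_end . u at theta = 0

    out = np.full(len(U), cap_deg)
    violated = f0 < cos_limit
    out[violated] = 0.0

    R = np.hypot(A, B)
    ok = ~violated & (R > 1e-15)
    with np.errstate(divide="ignore", invalid="ignore"):
        C = (cos_limit - K) / np.where(R > 1e-15, R, 1.0)
    cross = ok & (np.abs(C) <= 1.0)
    th0 = np.arctan2(B[cross], A[cross])
    a = np.arccos(np.clip(C[cross], -1.0, 1.0))
    cands = np.stack([th0 - a, th0 + a], axis=0) % (2 * np.pi)
    cands[cands < 1e-12] = 2 * np.pi
    theta = np.degrees(cands.min(axis=0))
    out[cross] = np.minimum(theta, cap_deg)
    return out


def _primary_path_vectors(pose: StemPose, primary_kind: str,
                          primary_deg: float, neck_axis_distal: np.ndarray,
                          step_deg: float):
    """Distal neck axis along the primary motion, plus the end rotation."""
    motion = JointMotion(primary_kind, primary_deg, "internal_rotation", 0.0)
    path = motion_path(pose, motion, step_deg=step_deg)
    m_path = path.matrices @ neck_axis_distal
    m_end = m_path[-1]
    shaft = path.matrices[-1] @ SHAFT_AXIS
    return m_path, m_end, shaft


def max_secondary_rotation(
    cup: CupOrientation,
    pose: StemPose,
    head: HeadSpec,
    liner: LinerSpec,
    neck_width_mm: float,
    neck_axis_distal: np.ndarray,
    primary: tuple[str, float],
    secondary_kind: str,
    path_step_deg: float = 3.0,
    cap_deg: float = SENTINEL_DEG,
) -> float:
    """Maximum secondary rotation (deg) before prosthetic impingement.

    Returns 0 when the primary motion alone violates the safe cone at any
    sampled station and ``cap_deg`` when no violation occurs within the
    physical range.
    """
    phi, gamma = cone_half_angles(head, liner, neck_width_mm)
    cos_limit = np.cos(np.radians(phi - gamma))
    m_path, m_end, shaft = _primary_path_vectors(
        pose, primary[0], primary[1], neck_axis_distal, path_step_deg
    )
    u = cup.axis()
    if (m_path @ u).min() < cos_limit:
        return 0.0
    sign = secondary_sign(secondary_kind)
    return float(
        _first_cone_exit(u[None, :], np.array([cos_limit]), m_end, shaft,
                         sign, cap_deg)[0]
    )


def _resolve_neck_width(source, alpha, beta, b: float, side: str):
    """Neck width from a database, a callable or a constant."""
    if isinstance(source, NeckWidthDatabase):
        return source.query(alpha, beta, b, side)
    if callable(source):
        return source(alpha, beta, b, side)
    return np.broadcast_to(float(source), np.shape(np.asarray(alpha))) \
        if np.ndim(alpha) else float(source)


def achieved_secondary_grid(
    alpha,
    beta,
    pose: StemPose,
    head: HeadSpec,
    liner: LinerSpec,
    neck_width_source,
    side: str,
    target: ROMTarget,
    neck_axis_distal: np.ndarray,
    path_step_deg: float = 3.0,
) -> np.ndarray:
    """Vectorised achieved secondary rotation over cup-orientation arrays."""
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    shape = np.broadcast_shapes(alpha.shape, beta.shape)
    A = np.broadcast_to(alpha, shape).ravel()
    B = np.broadcast_to(beta, shape).ravel()
    U = cup_axis_grid(A, B)

    n = np.asarray(
        _resolve_neck_width(neck_width_source, A, B, pose.anteversion_deg, side),
        dtype=float,
    ).ravel()
    n = np.broadcast_to(n, A.shape)
    # grid evaluation is total: cells where the neck cannot clear the cup
    # opening (gamma >= phi) simply achieve zero motion instead of raising
    r = head.radius_mm
    phi = np.degrees(np.arccos(np.clip((liner.depth_mm - r) / r, -1.0, 1.0)))
    gamma = np.degrees(np.arcsin(np.clip(n / (2.0 * r), 0.0, 1.0)))
    feasible_geom = gamma < phi
    cos_limit = np.where(
        feasible_geom, np.cos(np.radians(phi - gamma)), 2.0  # unreachable
    )

    motion = target.motion(side)
    m_path, m_end, shaft = _primary_path_vectors(
        pose, motion.primary, motion.primary_deg, neck_axis_distal,
        path_step_deg,
    )
    primary_ok = (m_path @ U.T).min(axis=0) >= cos_limit
    theta = _first_cone_exit(
        U, cos_limit, m_end, shaft, secondary_sign(motion.secondary)
    )
    return np.where(primary_ok, theta, 0.0).reshape(shape)


def achieved_rom(
    cup: CupOrientation,
    pose: StemPose,
    head: HeadSpec,
    liner: LinerSpec,
    neck_width_source,
    target: ROMTarget,
    neck_axis_distal: np.ndarray,
) -> tuple[float, float]:
    """(achieved IR at target flexion, achieved ER at target extension)."""
    vals = []
    for side in (FLEXION_SIDE, EXTENSION_SIDE):
        vals.append(
            float(
                achieved_secondary_grid(
                    cup.inclination_deg, cup.anteversion_deg, pose, head,
                    liner, neck_width_source, side, target, neck_axis_distal,
                )
            )
        )
    return vals[0], vals[1]


@dataclass
class ImpingementBoundary:
    """Cup orientations at which the target ROM is exactly met."""

    side: str
    target: ROMTarget
    points: list = field(default_factory=list)  # (alpha, beta), sorted by alpha
    all_crossings: dict = field(default_factory=dict)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(self.side, a, b) for a, b in self.points],
            columns=["side", "alpha_deg", "beta_deg"],
        )

    def to_csv(self, path) -> None:
        self.as_frame().to_csv(path, index=False, float_format="%.6f")

    def beta_at(self, alpha: float) -> float | None:
        for a, b in self.points:
            if abs(a - alpha) < 1e-9:
                return b
        return None


def _scan_roots(g, lo: float, hi: float, scan_step: float,
                tol: float) -> list[tuple[float, int]]:
    """Sign-change roots of g on [lo, hi] via coarse scan + Brent.

    Returns (root, direction) pairs, direction +1 for a negative-to-positive
    crossing and -1 for the reverse, in increasing order."""
    xs = np.arange(lo, hi + 1e-9, scan_step)
    if xs[-1] < hi - 1e-9:
        xs = np.append(xs, hi)
    vals = np.array([g(x) for x in xs])
    roots = []
    for i in range(len(xs) - 1):
        if vals[i] == 0.0:
            roots.append((float(xs[i]), 1 if vals[i + 1] > 0 else -1))
        elif vals[i] * vals[i + 1] < 0:
            roots.append(
                (
                    float(brentq(g, xs[i], xs[i + 1], xtol=tol)),
                    1 if vals[i + 1] > vals[i] else -1,
                )
            )
    if vals[-1] == 0.0:
        roots.append((float(xs[-1]), 1 if vals[-2] < 0 else -1))
    return roots


def solve_boundary(
    target: ROMTarget,
    pose: StemPose,
    head: HeadSpec,
    liner: LinerSpec,
    neck_width_source,
    side: str,
    alphas,
    neck_axis_distal: np.ndarray,
    beta_range: tuple[float, float] = (0.0, 60.0),
    scan_step_deg: float = 2.0,
    tol_deg: float = 0.01,
) -> ImpingementBoundary:
    """Per cup inclination, root-find the anteversion meeting the target.

    The boundary is the *principal* crossing — the one the colour map draws:
    on the flexion side orientations left of the curve (lower anteversion)
    impinge, so the boundary is the first unsatisfied-to-satisfied crossing
    scanning up in anteversion; on the extension side orientations right of
    the curve impinge, so it is the first satisfied-to-unsatisfied crossing.
    Inclinations without such a crossing are recorded as absent; all sign
    changes found are kept in ``all_crossings``.
    """
    boundary = ImpingementBoundary(side=side, target=target)
    tsec = target.secondary_target(side)
    want_dir = 1 if side == FLEXION_SIDE else -1

    def g_at(alpha):
        def g(beta):
            return (
                float(
                    achieved_secondary_grid(
                        alpha, beta, pose, head, liner, neck_width_source,
                        side, target, neck_axis_distal,
                    )
                )
                - tsec
            )
        return g

    for alpha in np.asarray(alphas, dtype=float):
        roots = _scan_roots(g_at(float(alpha)), beta_range[0], beta_range[1],
                            scan_step_deg, tol_deg)
        if not roots:
            continue
        boundary.all_crossings[float(alpha)] = [r for r, _ in roots]
        principal = [r for r, d in roots if d == want_dir]
        if principal:
            boundary.points.append((float(alpha), float(principal[0])))
    boundary.points.sort()
    return boundary


def solve_boundary_alpha(
    target: ROMTarget,
    pose: StemPose,
    head: HeadSpec,
    liner: LinerSpec,
    neck_width_source,
    side: str,
    betas,
    neck_axis_distal: np.ndarray,
    alpha_range: tuple[float, float] = (0.0, 60.0),
    scan_step_deg: float = 2.0,
    tol_deg: float = 0.01,
) -> dict[float, list[float]]:
    """Transposed solve: inclination roots at fixed anteversions.

    Used by the validation harness to express boundary disagreement in the
    inclination direction; returns {beta: [alpha roots]} (possibly empty)."""
    tsec = target.secondary_target(side)
    out: dict[float, list[float]] = {}
    for beta in np.asarray(betas, dtype=float):
        def g(alpha, _beta=float(beta)):
            return (
                float(
                    achieved_secondary_grid(
                        alpha, _beta, pose, head, liner, neck_width_source,
                        side, target, neck_axis_distal,
                    )
                )
                - tsec
            )
        out[float(beta)] = [
            r for r, _ in _scan_roots(
                g, alpha_range[0], alpha_range[1], scan_step_deg, tol_deg
            )
        ]
    return out
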