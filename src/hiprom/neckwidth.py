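"""Neck-width-at-impingement database: collision sweeps + TPS surfaces.

The cone-overlap ROM formula needs the neck width n at the impingement
level, which varies with cup orientation and stem anteversion for
trapezoidal necks.  This module builds n by driving the combined motion
(flexion then internal rotation on the flexion side; extension then external
rotation on the extension side) at every cup orientation of a grid until the
first mesh interference, recording n at the contact point, and then fitting
an exact thin-plate-spline surface n(alpha, beta) per stem-anteversion slice
and side.  Queries at arbitrary stem anteversion blend the two bracketing
slices linearly, which matches the validation design probing the slice
midpoints.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import RBFInterpolator

from .collision import InterferenceDetector
from .implants import ImplantAssembly
from .kinematics import CupOrientation, JointMotion, StemPose, motion_path

__all__ = [
    "FLEXION_SIDE",
    "EXTENSION_SIDE",
    "SIDES",
    "NeckWidthSample",
    "ThinPlateSplineSurface",
    "fit_tps",
    "simulate_neck_width",
    "NeckWidthDatabase",
]

log = logging.getLogger(__name__)

FLEXION_SIDE = "flexion_side"
EXTENSION_SIDE = "extension_side"
SIDES = (FLEXION_SIDE, EXTENSION_SIDE)

#: motion kinds driven on each side
SIDE_MOTIONS = {
    FLEXION_SIDE: ("flexion", "internal_rotation"),
    EXTENSION_SIDE: ("extension", "external_rotation"),
}

#: primary reference angle at which the secondary rotation is driven
DEFAULT_PRIMARY_DEG = {FLEXION_SIDE: 90.0, EXTENSION_SIDE: 10.0}

#: cap on the secondary sweep — beyond this the joint never impinges
SECONDARY_SWEEP_CAP_DEG = 170.0


@dataclass(frozen=True)
class NeckWidthSample:
    stem_anteversion_deg: float
    cup_inclination_deg: float
    cup_anteversion_deg: float
    side: str
    neck_width_mm: float
    contact_site: str
    primary_deg: float
    secondary_deg: float


class ThinPlateSplineSurface:
    """Exact thin-plate-spline interpolant over (alpha, beta) knots.

    Kernel rho^2 log rho plus an affine tail, zero smoothing: interpolates
    every knot exactly and reproduces affine functions exactly.  Duplicate
    knots are dropped before fitting.
    """

    def __init__(self, knots: np.ndarray, values: np.ndarray):
        knots = np.asarray(knots, dtype=float)
        values = np.asarray(values, dtype=float)
        _, idx = np.unique(np.round(knots, 9), axis=0, return_index=True)
        idx = np.sort(idx)
        knots, values = knots[idx], values[idx]
        if len(knots) < 3:
            raise ValueError("TPS fit needs at least 3 distinct knots")
        centred = knots - knots.mean(axis=0)
        if np.linalg.matrix_rank(centred, tol=1e-9) < 2:
            raise ValueError("TPS fit needs non-collinear knots")
        self.knots = knots
        self.values = values
        self._rbf = RBFInterpolator(
            knots, values, kernel="thin_plate_spline", smoothing=0.0, degree=1
        )

    def __call__(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return self._rbf(pts)


def fit_tps(samples: list[NeckWidthSample]) -> ThinPlateSplineSurface:
    """TPS surface n(alpha, beta) from one slice's samples."""
    knots = np.array(
        [[s.cup_inclination_deg, s.cup_anteversion_deg] for s in samples]
    )
    values = np.array([s.neck_width_mm for s in samples])
    return ThinPlateSplineSurface(knots, values)


def _bisect_first_contact(detector, cup, matrix_fn, lo, hi, tol):
    """Shrink [lo, hi] (lo clear, hi interfering) to within tol degrees."""
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if detector.interferes(matrix_fn(mid), cup):
            hi = mid
        else:
            lo = mid
    return lo, hi


def simulate_neck_width(
    assembly: ImplantAssembly,
    pose: StemPose,
    side: str,
    alphas=None,
    betas=None,
    primary_deg: float | None = None,
    secondary_max_deg: float = SECONDARY_SWEEP_CAP_DEG,
    coarse_step_deg: float = 2.0,
    bisect_tol_deg: float = 0.05,
    detector: InterferenceDetector | None = None,
) -> list[NeckWidthSample]:
    """Collision sweep over a cup-orientation grid for one side and pose.

    At each cup orientation the motion is driven from neutral in coarse
    steps; the first interfering step is refined by bisection and the neck
    width recorded at the contact point.  Orientations that never impinge
    within the secondary cap are censored (no sample); orientations already
    interfering at neutral are degenerate and skipped with a warning.
    """
    if side not in SIDES:
        raise ValueError(f"unknown side {side!r}")
    alphas = np.arange(0.0, 61.0, 10.0) if alphas is None else np.asarray(alphas)
    betas = np.arange(0.0, 61.0, 10.0) if betas is None else np.asarray(betas)
    if primary_deg is None:
        primary_deg = DEFAULT_PRIMARY_DEG[side]
    det = detector or InterferenceDetector(assembly)
    pk, sk = SIDE_MOTIONS[side]
    motion = JointMotion(pk, primary_deg, sk, secondary_max_deg)
    path = motion_path(pose, motion, step_deg=coarse_step_deg)

    # rim polar angle about the cup axis: the chord the rim must clear at
    # the contact event subtends gamma = phi - angle(neck axis, cup axis)
    # at the head centre, giving n = 2 r sin(gamma).  For cylindrical necks
    # this is the section diameter; for trapezoidal sections it is the
    # silhouette width actually engaged by the rim (corner contacts included).
    r_head = assembly.head.radius_mm
    phi = np.arccos(
        np.clip((assembly.liner.depth_mm - r_head) / r_head, -1.0, 1.0)
    )

    def effective_width(r_hit: np.ndarray, u: np.ndarray) -> float:
        m_axis = r_hit @ assembly.neck_axis_distal
        angle = np.arccos(np.clip(np.dot(m_axis, u), -1.0, 1.0))
        gamma = np.clip(phi - angle, 1e-6, np.pi / 2)
        return float(2.0 * r_head * np.sin(gamma))

    t0 = time.perf_counter()
    samples: list[NeckWidthSample] = []
    for alpha in alphas:
        for beta in betas:
            cup = CupOrientation(float(alpha), float(beta))
            flags = det.interferes(path.matrices, cup)
            if flags[0]:
                log.warning(
                    "interpenetration at neutral pose for cup (%.0f, %.0f); "
                    "orientation excluded", alpha, beta,
                )
                continue
            hits = np.flatnonzero(flags)
            if len(hits) == 0:
                continue  # censored: never impinges within the sweep
            k = int(hits[0])
            if k < path.n_primary:
                a_lo = path.primary_angles[k - 1]
                a_hi = path.primary_angles[k]
                lo, hi = _bisect_first_contact(
                    det, cup, path.primary_matrix, a_lo, a_hi, bisect_tol_deg
                )
                prim, sec = hi, 0.0
                r_hit = path.primary_matrix(hi)
            else:
                j = k - path.n_primary
                a_lo = path.secondary_angles[j - 1] if j > 0 else 0.0
                a_hi = path.secondary_angles[j]
                lo, hi = _bisect_first_contact(
                    det, cup, path.secondary_matrix, a_lo, a_hi, bisect_tol_deg
                )
                prim, sec = primary_deg, hi
                r_hit = path.secondary_matrix(hi)
            info = det.contact(r_hit, cup)
            if info is None:  # numerically grazing; treat as censored
                continue
            samples.append(
                NeckWidthSample(
                    stem_anteversion_deg=float(pose.anteversion_deg),
                    cup_inclination_deg=float(alpha),
                    cup_anteversion_deg=float(beta),
                    side=side,
                    neck_width_mm=effective_width(r_hit, cup.axis()),
                    contact_site=info.site,
                    primary_deg=float(prim),
                    secondary_deg=float(sec),
                )
            )
    log.info(
        "sweep side=%s b=%.0f: %d/%d orientations impinged in %.2fs",
        side, pose.anteversion_deg, len(samples), alphas.size * betas.size,
        time.perf_counter() - t0,
    )
    return samples


_CSV_COLUMNS = [
    "side", "b", "alpha", "beta", "n_mm", "site", "primary_deg", "secondary_deg",
]


@dataclass
class NeckWidthDatabase:
    """Scattered neck-width samples plus per-(slice, side) TPS surfaces."""

    parameter_hash: str
    samples: pd.DataFrame
    width_range: tuple[float, float]
    meta: dict = field(default_factory=dict)
    _surfaces: dict = field(default_factory=dict, repr=False)

    @classmethod
    def build(
        cls,
        assembly: ImplantAssembly,
        slices=(-40.0, -20.0, 0.0, 20.0, 40.0, 60.0),
        sides=SIDES,
        alphas=None,
        betas=None,
        adduction_deg: float = 6.0,
        stem_flexion_deg: float = 0.0,
        primary_deg: dict | None = None,
        coarse_step_deg: float = 2.0,
        bisect_tol_deg: float = 0.05,
    ) -> "NeckWidthDatabase":
        alphas = np.arange(0.0, 61.0, 10.0) if alphas is None else np.asarray(alphas, float)
        betas = np.arange(0.0, 61.0, 10.0) if betas is None else np.asarray(betas, float)
        primary_deg = dict(DEFAULT_PRIMARY_DEG) if primary_deg is None else primary_deg
        det = InterferenceDetector(assembly)
        rows = []
        for side in sides:
            for b in slices:
                pose = StemPose(
                    anteversion_deg=float(b),
                    adduction_deg=adduction_deg,
                    flexion_deg=stem_flexion_deg,
                )
                for s in simulate_neck_width(
                    assembly, pose, side, alphas=alphas, betas=betas,
                    primary_deg=primary_deg[side],
                    coarse_step_deg=coarse_step_deg,
                    bisect_tol_deg=bisect_tol_deg, detector=det,
                ):
                    rows.append(
                        (s.side, s.stem_anteversion_deg, s.cup_inclination_deg,
                         s.cup_anteversion_deg, s.neck_width_mm, s.contact_site,
                         s.primary_deg, s.secondary_deg)
                    )
        df = pd.DataFrame(rows, columns=_CSV_COLUMNS)
        df = df.sort_values(["side", "b", "alpha", "beta"]).reset_index(drop=True)
        meta = {
            "slices": [float(b) for b in slices],
            "alphas": alphas.tolist(),
            "betas": betas.tolist(),
            "adduction_deg": adduction_deg,
            "stem_flexion_deg": stem_flexion_deg,
            "primary_deg": {k: float(v) for k, v in primary_deg.items()},
            "coarse_step_deg": coarse_step_deg,
            "bisect_tol_deg": bisect_tol_deg,
        }
        return cls(
            parameter_hash=assembly.parameter_hash(),
            samples=df,
            width_range=assembly.width_range(),
            meta=meta,
        )

    # -- surfaces ----------------------------------------------------------

    def slices(self, side: str) -> np.ndarray:
        return np.sort(
            self.samples.loc[self.samples["side"] == side, "b"].unique()
        )

    def surface(self, side: str, b: float) -> ThinPlateSplineSurface:
        key = (side, float(b))
        if key not in self._surfaces:
            sub = self.samples[
                (self.samples["side"] == side) & (self.samples["b"] == b)
            ]
            if len(sub) < 3:
                raise ValueError(
                    f"slice (side={side}, b={b}) has {len(sub)} samples; "
                    "cannot fit a TPS surface"
                )
            self._surfaces[key] = ThinPlateSplineSurface(
                sub[["alpha", "beta"]].to_numpy(), sub["n_mm"].to_numpy()
            )
        return self._surfaces[key]

    # -- queries -----------------------------------------------------------

    def query(self, alpha, beta, b: float, side: str) -> np.ndarray:
        """Neck width n (mm) at cup (alpha, beta) and stem anteversion b.

        Evaluates the TPS surfaces of the two bracketing stem-anteversion
        slices and blends linearly in b; results are clamped into the stem's
        physical width range.  Queries outside the database domain raise.
        """
        alpha = np.asarray(alpha, dtype=float)
        beta = np.asarray(beta, dtype=float)
        a_lo, a_hi = min(self.meta["alphas"]), max(self.meta["alphas"])
        b_lo, b_hi = min(self.meta["betas"]), max(self.meta["betas"])
        eps = 1e-9
        if (alpha.min() < a_lo - eps or alpha.max() > a_hi + eps
                or beta.min() < b_lo - eps or beta.max() > b_hi + eps):
            raise ValueError("query outside the cup-orientation domain")
        slc = self.slices(side)
        if not (slc.min() - eps <= b <= slc.max() + eps):
            raise ValueError("stem anteversion outside the database slices")
        pts = np.column_stack([np.ravel(alpha), np.ravel(beta)])
        i = int(np.searchsorted(slc, b + eps) - 1)
        i = max(0, min(i, len(slc) - 1))
        if abs(slc[i] - b) < eps or i == len(slc) - 1:
            vals = self.surface(side, slc[i])(pts)
        else:
            lo_v = self.surface(side, slc[i])(pts)
            hi_v = self.surface(side, slc[i + 1])(pts)
            t = (b - slc[i]) / (slc[i + 1] - slc[i])
            vals = (1.0 - t) * lo_v + t * hi_v
        vals = np.clip(vals, self.width_range[0], self.width_range[1])
        return vals.reshape(np.shape(alpha)) if np.shape(alpha) else float(vals[0])

    # -- persistence -------------------------------------------------------

    def write(self, out_dir) -> None:
        """CSV samples plus JSON metadata; diff-able and deterministic."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.samples.to_csv(
            out / "neck_width.csv", index=False, float_format="%.6f"
        )
        meta = dict(self.meta)
        meta["parameter_hash"] = self.parameter_hash
        meta["width_range"] = list(self.width_range)
        (out / "meta.json").write_text(
            json.dumps(meta, indent=2, sort_keys=True) + "\n"
        )

    @classmethod
    def read(cls, in_dir) -> "NeckWidthDatabase":
        path = Path(in_dir)
        meta = json.loads((path / "meta.json").read_text())
        df = pd.read_csv(path / "neck_width.csv")
        width_range = tuple(meta.pop("width_range"))
        phash = meta.pop("parameter_hash")
        return cls(
            parameter_hash=phash, samples=df,
            width_range=width_range, meta=meta,
        )
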