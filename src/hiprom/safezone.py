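"""Safe-zone maps: satisfaction field over cup orientations and rendering.

A cup orientation is "green" when both combined target motions (IR at
flexion, ER at extension) complete without prosthetic impingement.  The map
is evaluated at cell centres of a regular (inclination, anteversion) grid;
the green area is the satisfied cell count times the cell area, in square
degrees.  Rendering reproduces the standard presentation: green/red colour
map, the two impingement boundary curves, and a black reference box at
30-50 deg inclination x 10-30 deg anteversion marking commonly accepted cup
positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")  # noqa: E402 - headless rendering
import matplotlib.pyplot as plt
import numpy as np

from .implants import ImplantAssembly, SITE_TRUNNION
from .kinematics import StemPose
from .neckwidth import EXTENSION_SIDE, FLEXION_SIDE, NeckWidthDatabase
from .rom import ROMTarget, achieved_secondary_grid, solve_boundary

__all__ = ["REFERENCE_BOX", "SafeZoneMap", "evaluate_map", "offset_study", "render_map"]

log = logging.getLogger(__name__)

#: (inclination lo, hi), (anteversion lo, hi) of the reference box, degrees
REFERENCE_BOX = ((30.0, 50.0), (10.0, 30.0))


@dataclass
class SafeZoneMap:
    """Boolean satisfaction grid over cup orientations."""

    alphas: np.ndarray  # cell-centre inclinations
    betas: np.ndarray  # cell-centre anteversions
    step_deg: float
    satisfied: np.ndarray  # shape (len(alphas), len(betas))
    boundaries: dict = field(default_factory=dict)
    target: ROMTarget | None = None
    pose: StemPose | None = None
    reference_box: tuple = REFERENCE_BOX

    @property
    def green_area_deg2(self) -> float:
        return float(self.satisfied.sum()) * self.step_deg**2

    def green_centroid(self) -> tuple[float, float] | None:
        """(mean inclination, mean anteversion) of the green zone."""
        ii, jj = np.nonzero(self.satisfied)
        if len(ii) == 0:
            return None
        return float(self.alphas[ii].mean()), float(self.betas[jj].mean())

    def to_json(self, path) -> None:
        """Serialise grid spec, satisfaction array and boundary curves."""
        import json

        payload = {
            "alphas_deg": self.alphas.tolist(),
            "betas_deg": self.betas.tolist(),
            "step_deg": self.step_deg,
            "satisfied": self.satisfied.astype(int).tolist(),
            "green_area_deg2": self.green_area_deg2,
            "reference_box": self.reference_box,
            "target": str(self.target) if self.target else None,
            "boundaries": {
                side: bd.points for side, bd in self.boundaries.items()
            },
        }
        from pathlib import Path as _P

        _P(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path) -> "SafeZoneMap":
        import json
        from pathlib import Path as _P

        d = json.loads(_P(path).read_text())
        from .rom import ImpingementBoundary
        from .config import parse_target

        target = parse_target(d["target"]) if d.get("target") else None
        boundaries = {
            side: ImpingementBoundary(
                side=side, target=target,
                points=[tuple(p) for p in pts],
            )
            for side, pts in d.get("boundaries", {}).items()
        }
        return cls(
            alphas=np.asarray(d["alphas_deg"]),
            betas=np.asarray(d["betas_deg"]),
            step_deg=float(d["step_deg"]),
            satisfied=np.asarray(d["satisfied"], dtype=bool),
            boundaries=boundaries,
            target=target,
            reference_box=tuple(tuple(b) for b in d["reference_box"]),
        )


def evaluate_map(
    target: ROMTarget,
    pose: StemPose,
    assembly: ImplantAssembly,
    neck_width_source,
    step_deg: float = 1.0,
    alpha_range: tuple[float, float] = (0.0, 60.0),
    beta_range: tuple[float, float] = (0.0, 60.0),
    with_boundaries: bool = True,
) -> SafeZoneMap:
    """Classify every grid cell (at its centre) against the target ROM."""
    head, liner = assembly.head, assembly.liner
    alphas = np.arange(alpha_range[0] + step_deg / 2, alpha_range[1], step_deg)
    betas = np.arange(beta_range[0] + step_deg / 2, beta_range[1], step_deg)
    A, B = np.meshgrid(alphas, betas, indexing="ij")

    satisfied = np.ones(A.shape, dtype=bool)
    for side in (FLEXION_SIDE, EXTENSION_SIDE):
        achieved = achieved_secondary_grid(
            A, B, pose, head, liner, neck_width_source, side, target,
            assembly.neck_axis_distal,
        )
        satisfied &= achieved >= target.secondary_target(side)

    boundaries = {}
    if with_boundaries:
        for side in (FLEXION_SIDE, EXTENSION_SIDE):
            boundaries[side] = solve_boundary(
                target, pose, head, liner, neck_width_source, side,
                alphas, assembly.neck_axis_distal, beta_range=beta_range,
            )
    m = SafeZoneMap(
        alphas=alphas, betas=betas, step_deg=step_deg, satisfied=satisfied,
        boundaries=boundaries, target=target, pose=pose,
    )
    if m.green_area_deg2 == 0.0:
        log.warning("empty green zone for target %s at b=%.1f",
                    target, pose.anteversion_deg)
    return m


def offset_study(
    assembly_factory,
    offsets=(-4.0, 0.0, 4.0, 8.0),
    target: ROMTarget | None = None,
    pose: StemPose | None = None,
    step_deg: float = 2.0,
    db_grid_step_deg: float = 10.0,
) -> dict:
    """Green-zone area per modular head offset, with trunnion-contact flags.

    ``assembly_factory(offset_mm)`` must return an :class:`ImplantAssembly`.
    Each offset gets its own single-slice neck-width database at the study's
    stem anteversion (a pure TPS evaluation, no cross-slice blending).
    """
    target = target or ROMTarget(30.0, 90.0, 10.0, 10.0)
    pose = pose or StemPose(anteversion_deg=10.0)
    grid = np.arange(0.0, 61.0, db_grid_step_deg)
    results: dict[float, dict] = {}
    for off in offsets:
        assembly = assembly_factory(float(off))
        db = NeckWidthDatabase.build(
            assembly, slices=(pose.anteversion_deg,),
            alphas=grid, betas=grid,
            adduction_deg=pose.adduction_deg,
            stem_flexion_deg=pose.flexion_deg,
        )
        zone = evaluate_map(
            target, pose, assembly, db, step_deg=step_deg,
            with_boundaries=False,
        )
        results[float(off)] = {
            "green_area_deg2": zone.green_area_deg2,
            "trunnion_contact": bool(
                (db.samples["site"] == SITE_TRUNNION).any()
            ),
        }
    return results


def render_map(zone: SafeZoneMap, out_path, anteversion_on_x: bool = True):
    """Render the colour map with boundaries and the black reference box."""
    fig, ax = plt.subplots(figsize=(6.0, 5.0))
    half = zone.step_deg / 2
    a_edges = np.concatenate([zone.alphas - half, [zone.alphas[-1] + half]])
    b_edges = np.concatenate([zone.betas - half, [zone.betas[-1] + half]])
    colors = np.where(zone.satisfied, 1.0, 0.0)
    cmap = matplotlib.colors.ListedColormap(["#c62828", "#2e7d32"])
    (incl_box, av_box) = zone.reference_box
    if anteversion_on_x:
        ax.pcolormesh(b_edges, a_edges, colors, cmap=cmap, vmin=0, vmax=1)
        for bd in zone.boundaries.values():
            if bd.points:
                pts = np.array(bd.points)
                ax.plot(pts[:, 1], pts[:, 0], "k-", lw=1.2)
        ax.add_patch(
            plt.Rectangle(
                (av_box[0], incl_box[0]), av_box[1] - av_box[0],
                incl_box[1] - incl_box[0], fill=False, ec="black", lw=2.0,
            )
        )
        ax.set_xlabel("cup anteversion (deg)")
        ax.set_ylabel("cup inclination (deg)")
    else:
        ax.pcolormesh(a_edges, b_edges, colors.T, cmap=cmap, vmin=0, vmax=1)
        for bd in zone.boundaries.values():
            if bd.points:
                pts = np.array(bd.points)
                ax.plot(pts[:, 0], pts[:, 1], "k-", lw=1.2)
        ax.add_patch(
            plt.Rectangle(
                (incl_box[0], av_box[0]), incl_box[1] - incl_box[0],
                av_box[1] - av_box[0], fill=False, ec="black", lw=2.0,
            )
        )
        ax.set_xlabel("cup inclination (deg)")
        ax.set_ylabel("cup anteversion (deg)")
    if zone.target is not None:
        ax.set_title(f"impingement-free zone, target {zone.target}")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
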