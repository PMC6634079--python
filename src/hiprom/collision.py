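"""Mesh interference detection between the stem and the liner.

The test is specialised to this problem and fully vectorised: the stem is
represented by its mesh vertices (prefiltered once to the band of distances
from the rotation centre that can physically reach the liner — distances are
invariant under the hip rotations, which are all about the origin), and the
liner by the revolved solid of the meridian polygon its mesh is built from.
A point is interfering when it lies strictly inside the other part's solid.
Both directions are tested: stem vertices against the liner solid, and the
liner's rim-circle vertices against the stem's swept-profile solid, so sharp
rim-edge-into-face contacts are not missed.

Accuracy scales with mesh resolution through the vertex sampling and the
meridian discretisation; the convergence tests double the resolution and
check the located boundaries move by far less than the solver tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.path import Path

from .implants import (
    ImplantAssembly,
    SITE_NECK,
    SITE_TRUNNION,
    liner_profile_2d,
)
from .kinematics import CupOrientation, cup_axis

__all__ = ["ContactInfo", "InterferenceDetector"]


@dataclass(frozen=True)
class ContactInfo:
    """First-interference information, in the neutral stem frame."""

    point_stem_frame: np.ndarray
    neck_width_mm: float
    site: str
    depth_mm: float


def _orthonormal_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors spanning the plane orthogonal to u (deterministic)."""
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(u, ref)) > 0.99:
        ref = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(ref, u)
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(u, e1)


class InterferenceDetector:
    """Stem-vs-liner interference for a fixed assembly.

    Stem motion is supplied as rotation matrices (stem frame -> pelvic
    frame); the liner is fixed at a cup orientation.  Batched queries over
    whole motion paths are a single vectorised pass.
    """

    def __init__(self, assembly: ImplantAssembly, margin_mm: float = 1.0):
        self.assembly = assembly
        liner = assembly.liner
        self.cavity_radius = liner.inner_radius_mm
        self.w_rim = liner.rim_plane_mm
        profile = liner_profile_2d(liner, assembly.resolution)
        self._liner_path = Path(profile, closed=False)

        # stem samples: mesh vertices that can ever reach the liner material.
        # Rotations preserve |v|, so the band test is done once.
        verts = np.asarray(assembly.stem_mesh.vertices)
        dist = np.linalg.norm(verts, axis=1)
        reach = np.sqrt(
            liner.rim_outer_radius_mm**2 + (liner.inner_radius_mm + 3.0) ** 2
        )
        keep = (dist >= self.cavity_radius - margin_mm) & (dist <= reach + margin_mm)
        self.stem_points = verts[keep]
        self.stem_dist = dist[keep]
        if len(self.stem_points) == 0:
            raise ValueError("no stem vertices within reach of the liner")

        # per-sample neck width and contact site, fixed in the stem frame
        m = assembly.neck_axis_distal
        axial = self.stem_points @ m
        radial = self.stem_points - axial[:, None] * m[None, :]
        self.stem_widths = 2.0 * np.linalg.norm(radial, axis=1)
        sigma = axial - assembly.s_tip
        self.stem_sites = np.where(
            sigma <= assembly.stem.neck.trunnion_length_mm, SITE_TRUNNION, SITE_NECK
        )

        # liner rim-circle samples in the liner's local frame (axis = +z)
        n_rim = 2 * assembly.resolution
        tau = np.linspace(0.0, 2 * np.pi, n_rim, endpoint=False)
        c = liner.rim_radius_mm
        self._rim_local = np.column_stack(
            [c * np.cos(tau), c * np.sin(tau), np.full(n_rim, self.w_rim)]
        )

        prof = assembly.stem.neck
        self._prof = prof
        self._m = m
        self._e_ap = assembly.e_ap
        self._e_pd = assembly.e_pd
        self._s_tip = assembly.s_tip

    # -- liner-side containment -------------------------------------------

    def _points_in_liner(self, pts: np.ndarray, u: np.ndarray,
                         dist: np.ndarray) -> np.ndarray:
        """Mask of pelvic-frame points inside the liner solid at cup axis u."""
        w = pts @ u
        rho_sq = np.maximum(dist * dist - w * w, 0.0)
        coords = np.column_stack([np.sqrt(rho_sq), w])
        return self._liner_path.contains_points(coords)

    # -- stem-side containment --------------------------------------------

    def _points_in_stem(self, q: np.ndarray) -> np.ndarray:
        """Mask of stem-frame points inside the trunnion/neck solid."""
        prof = self._prof
        axial = q @ self._m
        sigma = axial - self._s_tip
        x = q @ self._e_ap
        y = q @ self._e_pd
        rr = x * x + y * y

        on_tr = (sigma >= 0.0) & (sigma <= prof.trunnion_length_mm)
        r_tr = prof.trunnion_radius(sigma)
        in_tr = on_tr & (rr < r_tr * r_tr)

        on_nk = (sigma > prof.trunnion_length_mm) & (sigma <= prof.total_length_mm)
        h_ap, h_pd = prof.half_widths(sigma)
        c = prof.corner_radius_mm
        qx = np.abs(x) - (h_ap - c)
        qy = np.abs(y) - (h_pd - c)
        sdf = (
            np.hypot(np.maximum(qx, 0.0), np.maximum(qy, 0.0))
            + np.minimum(np.maximum(qx, qy), 0.0)
            - c
        )
        in_nk = on_nk & (sdf < 0.0)
        return in_tr | in_nk

    # -- public queries ----------------------------------------------------

    def interferes(self, rotations: np.ndarray, cup: CupOrientation) -> np.ndarray:
        """Boolean per rotation matrix: any interference at that stem pose.

        ``rotations`` is (3, 3) or (T, 3, 3), mapping stem frame -> pelvic.
        """
        R = np.asarray(rotations, dtype=float)
        single = R.ndim == 2
        if single:
            R = R[None]
        u = cup_axis(cup.inclination_deg, cup.anteversion_deg)

        out = np.zeros(len(R), dtype=bool)
        # stem vertices in the liner solid
        pts = np.einsum("tij,nj->tni", R, self.stem_points)
        w = pts @ u
        rho_sq = np.maximum(self.stem_dist[None, :] ** 2 - w * w, 0.0)
        coords = np.column_stack([np.sqrt(rho_sq).ravel(), w.ravel()])
        inside = self._liner_path.contains_points(coords).reshape(w.shape)
        out |= inside.any(axis=1)

        # liner rim vertices in the stem solid
        e1, e2 = _orthonormal_basis(u)
        rim_pelvic = (
            self._rim_local[:, 0:1] * e1[None, :]
            + self._rim_local[:, 1:2] * e2[None, :]
            + self._rim_local[:, 2:3] * u[None, :]
        )
        q = np.einsum("tji,nj->tni", R, rim_pelvic)  # R^T p
        in_stem = self._points_in_stem(q.reshape(-1, 3)).reshape(len(R), -1)
        out |= in_stem.any(axis=1)
        return out[0] if single else out

    def contact(self, rotation: np.ndarray,
                cup: CupOrientation) -> ContactInfo | None:
        """Contact details at an (ideally just-)interfering stem pose.

        Picks the deepest penetrating stem vertex; falls back to the deepest
        penetrating rim vertex (mapped to the stem frame) when the contact is
        a rim-edge-into-face event that the vertex sampling does not see.
        """
        R = np.asarray(rotation, dtype=float)
        u = cup_axis(cup.inclination_deg, cup.anteversion_deg)

        pts = self.stem_points @ R.T
        w = pts @ u
        rho_sq = np.maximum(self.stem_dist**2 - w * w, 0.0)
        coords = np.column_stack([np.sqrt(rho_sq), w])
        inside = self._liner_path.contains_points(coords)
        if inside.any():
            depth = np.minimum(
                self.w_rim - w[inside], self.stem_dist[inside] - self.cavity_radius
            )
            k = int(np.argmax(depth))
            idx = np.flatnonzero(inside)[k]
            return ContactInfo(
                point_stem_frame=self.stem_points[idx].copy(),
                neck_width_mm=float(self.stem_widths[idx]),
                site=str(self.stem_sites[idx]),
                depth_mm=float(max(depth[k], 0.0)),
            )

        e1, e2 = _orthonormal_basis(u)
        rim_pelvic = (
            self._rim_local[:, 0:1] * e1[None, :]
            + self._rim_local[:, 1:2] * e2[None, :]
            + self._rim_local[:, 2:3] * u[None, :]
        )
        q = rim_pelvic @ R  # R^T applied to rows
        in_stem = self._points_in_stem(q)
        if in_stem.any():
            from .implants import neck_width_at_contact

            cands = q[in_stem]
            # deepest along the neck-axis-perpendicular direction: use the
            # smallest clearance to the section boundary as a proxy
            k = 0
            p = cands[k]
            n, site = neck_width_at_contact(self.assembly, p)
            return ContactInfo(
                point_stem_frame=p.copy(), neck_width_mm=n, site=site, depth_mm=0.0
            )
        return None
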