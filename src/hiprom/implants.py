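"""Parametric implant geometry: stem neck/trunnion, modular head, liner.

The assembly frame has the head centre (= hip centre of rotation) at the
origin.  The stem's neck axis passes through the origin; stations along the
neck are measured from the head centre in the distal direction (toward the
trunnion, then the neck base at the stem shoulder).  Modular head offset
translates the whole stem along the neck axis: a longer offset pushes the
trunnion further from the head centre, exposing it to the liner rim, while a
short offset brings the wide neck base within reach — both phenomena the
impingement analysis must capture.

Cross-sections: modern stems have trapezoidal necks; these are modelled as
rounded rectangles with independent anterior-posterior (AP) and
proximal-distal (PD) half-widths that vary linearly from the trunnion
junction to the neck base.  Cylindrical necks are the degenerate case
(constant circular section) and make the cone-overlap formula exact, which
the validation suite exploits.

All lengths are millimetres, all angles degrees.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import trimesh

__all__ = [
    "HeadSpec",
    "LinerSpec",
    "NeckProfile",
    "StemSpec",
    "ImplantAssembly",
    "make_stem_mesh",
    "make_liner_mesh",
    "make_assembly",
    "neck_width_at_contact",
]

DEFAULT_RESOLUTION = 64

SITE_NECK = "neck"
SITE_TRUNNION = "trunnion"


@dataclass(frozen=True)
class HeadSpec:
    """Modular femoral head: radius and offset along the neck axis."""

    radius_mm: float
    offset_mm: float = 0.0

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise ValueError("head radius must be positive")


@dataclass(frozen=True)
class LinerSpec:
    """Acetabular liner: spherical cavity of given radius and depth.

    ``depth_mm`` is the axial distance from the flat rim face to the cavity
    pole; ``depth == inner_radius`` is a hemispherical liner, larger values
    describe lipped/deep profiles.
    """

    inner_radius_mm: float
    depth_mm: float
    rim_outer_radius_mm: float = 0.0

    def __post_init__(self):
        if self.inner_radius_mm <= 0:
            raise ValueError("liner inner radius must be positive")
        if not (0 < self.depth_mm <= 2 * self.inner_radius_mm):
            raise ValueError("liner depth must satisfy 0 < depth <= 2*radius")
        if self.rim_outer_radius_mm == 0.0:
            object.__setattr__(
                self, "rim_outer_radius_mm", self.inner_radius_mm + 5.0
            )
        if self.rim_outer_radius_mm <= self.inner_radius_mm:
            raise ValueError("rim outer radius must exceed the cavity radius")

    @property
    def rim_plane_mm(self) -> float:
        """Axial position of the rim face (cavity centre at 0, opening +)."""
        return self.depth_mm - self.inner_radius_mm

    @property
    def rim_radius_mm(self) -> float:
        """Radius of the rim circle (cavity edge)."""
        r, w = self.inner_radius_mm, self.rim_plane_mm
        return float(np.sqrt(r * r - w * w)) if abs(w) < r else 0.0


@dataclass(frozen=True)
class NeckProfile:
    """Cross-section profile of the neck and trunnion.

    Stations ``sigma`` are measured from the trunnion tip toward the neck
    base.  The trunnion occupies ``[0, trunnion_length_mm]`` as a circular
    frustum; the neck spans the next ``neck_length_mm`` with rounded-rectangle
    sections whose AP/PD full widths vary linearly between the junction and
    base values.
    """

    kind: str
    neck_length_mm: float
    ap_width_junction_mm: float
    ap_width_base_mm: float
    pd_width_junction_mm: float
    pd_width_base_mm: float
    corner_radius_mm: float
    trunnion_diameter_mm: float
    trunnion_length_mm: float = 6.0
    trunnion_tip_offset_mm: float = 4.0
    trunnion_taper_mm: float = 0.5

    def __post_init__(self):
        if self.kind not in ("cylindrical", "trapezoidal"):
            raise ValueError(f"unknown neck profile kind {self.kind!r}")
        widths = (
            self.ap_width_junction_mm,
            self.ap_width_base_mm,
            self.pd_width_junction_mm,
            self.pd_width_base_mm,
        )
        if any(w <= 0 for w in widths) or self.neck_length_mm <= 0:
            raise ValueError("neck widths and length must be positive")
        if self.corner_radius_mm <= 0 or 2 * self.corner_radius_mm > min(widths):
            raise ValueError("corner radius must be positive and fit the section")
        if self.kind == "cylindrical":
            if len(set(widths)) != 1:
                raise ValueError("cylindrical profiles have one constant width")
            if abs(self.trunnion_diameter_mm - widths[0]) > 1e-9:
                raise ValueError(
                    "cylindrical profiles have trunnion flush with the neck"
                )

    @classmethod
    def cylindrical(cls, width_mm: float, neck_length_mm: float = 30.0,
                    trunnion_tip_offset_mm: float = 4.0) -> "NeckProfile":
        return cls(
            kind="cylindrical",
            neck_length_mm=neck_length_mm,
            ap_width_junction_mm=width_mm,
            ap_width_base_mm=width_mm,
            pd_width_junction_mm=width_mm,
            pd_width_base_mm=width_mm,
            corner_radius_mm=width_mm / 2.0,
            trunnion_diameter_mm=width_mm,
            trunnion_length_mm=6.0,
            trunnion_tip_offset_mm=trunnion_tip_offset_mm,
            trunnion_taper_mm=0.0,
        )

    @property
    def total_length_mm(self) -> float:
        return self.trunnion_length_mm + self.neck_length_mm

    def half_widths(self, sigma) -> tuple[np.ndarray, np.ndarray]:
        """(AP, PD) half-widths of the neck section at station(s) sigma."""
        s = np.asarray(sigma, dtype=float)
        t = np.clip(
            (s - self.trunnion_length_mm) / self.neck_length_mm, 0.0, 1.0
        )
        h_ap = 0.5 * (
            self.ap_width_junction_mm
            + t * (self.ap_width_base_mm - self.ap_width_junction_mm)
        )
        h_pd = 0.5 * (
            self.pd_width_junction_mm
            + t * (self.pd_width_base_mm - self.pd_width_junction_mm)
        )
        return h_ap, h_pd

    def trunnion_radius(self, sigma) -> np.ndarray:
        """Circular trunnion frustum radius at station(s) sigma."""
        s = np.clip(np.asarray(sigma, dtype=float), 0, self.trunnion_length_mm)
        r_base = self.trunnion_diameter_mm / 2.0
        if self.trunnion_length_mm <= 0:
            return np.full_like(s, r_base)
        return r_base - self.trunnion_taper_mm * (1.0 - s / self.trunnion_length_mm)

    def width_fn(self, sigma) -> tuple[np.ndarray, np.ndarray]:
        """(AP, PD) full widths at station(s) sigma, trunnion included."""
        s = np.asarray(sigma, dtype=float)
        h_ap, h_pd = self.half_widths(s)
        on_tr = s <= self.trunnion_length_mm
        d_tr = 2.0 * self.trunnion_radius(s)
        return np.where(on_tr, d_tr, 2 * h_ap), np.where(on_tr, d_tr, 2 * h_pd)

    def width_range(self) -> tuple[float, float]:
        """Physical [min, max] of any cross-section width on the stem."""
        sig = np.linspace(0.0, self.total_length_mm, 200)
        ap, pd = self.width_fn(sig)
        return float(min(ap.min(), pd.min())), float(max(ap.max(), pd.max()))


@dataclass(frozen=True)
class StemSpec:
    """Femoral stem: neck-shaft angle plus the neck/trunnion profile."""

    neck: NeckProfile
    neck_shaft_angle_deg: float = 125.0
    supported_offsets_mm: tuple = (-4.0, 0.0, 4.0, 8.0)

    def __post_init__(self):
        if not (90.0 < self.neck_shaft_angle_deg < 180.0):
            raise ValueError("neck-shaft angle must be in (90, 180) degrees")


def _rounded_rect_radius(psi: np.ndarray, h_ap: float, h_pd: float,
                         c: float) -> np.ndarray:
    """Distance from the section centre to the rounded-rectangle boundary
    along direction (cos psi, sin psi); solved by bisection on the SDF."""
    d_ap, d_pd = np.cos(psi), np.sin(psi)
    lo = np.zeros_like(psi)
    hi = np.full_like(psi, np.hypot(h_ap, h_pd) + 1.0)

    def sdf(t):
        x, y = t * d_ap, t * d_pd
        qx = np.abs(x) - (h_ap - c)
        qy = np.abs(y) - (h_pd - c)
        return (
            np.hypot(np.maximum(qx, 0.0), np.maximum(qy, 0.0))
            + np.minimum(np.maximum(qx, qy), 0.0)
            - c
        )

    for _ in range(60):
        mid = 0.5 * (lo + hi)
        inside = sdf(mid) < 0.0
        lo = np.where(inside, mid, lo)
        hi = np.where(inside, hi, mid)
    return 0.5 * (lo + hi)


def neck_frame(neck_shaft_angle_deg: float):
    """(m_distal, e_ap, e_pd): distal neck axis from the head centre and the
    cross-section basis, in the neutral stem frame (right hip)."""
    e = np.radians(neck_shaft_angle_deg - 90.0)
    u_head = np.array([-np.cos(e), 0.0, np.sin(e)])  # toward head: medial-superior
    m = -u_head  # distal: lateral-inferior
    e_ap = np.array([0.0, 1.0, 0.0])
    e_pd = np.cross(m, e_ap)
    return m, e_ap, e_pd


def _tube_mesh(rings: list[np.ndarray]) -> trimesh.Trimesh:
    """Closed tube from ordered vertex rings (equal counts), capped by fans."""
    m = rings[0].shape[0]
    verts = np.concatenate(rings, axis=0)
    faces = []
    for i in range(len(rings) - 1):
        a, b = i * m, (i + 1) * m
        for j in range(m):
            k = (j + 1) % m
            faces.append([a + j, a + k, b + j])
            faces.append([b + j, a + k, b + k])
    c0 = len(verts)
    verts = np.vstack([verts, rings[0].mean(axis=0), rings[-1].mean(axis=0)])
    last = (len(rings) - 1) * m
    for j in range(m):
        k = (j + 1) % m
        faces.append([c0, k, j])  # tip cap
        faces.append([c0 + 1, last + j, last + k])  # base cap
    mesh = trimesh.Trimesh(vertices=verts, faces=np.array(faces), process=True)
    mesh.fix_normals()
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def make_stem_mesh(stem: StemSpec, head: HeadSpec,
                   resolution: int = DEFAULT_RESOLUTION) -> trimesh.Trimesh:
    """Watertight triangle mesh of the trunnion + neck in the assembly frame.

    The head centre is at the origin; the trunnion tip sits at
    ``trunnion_tip_offset + head.offset`` along the distal neck axis, so head
    offset rigidly shifts the exposed stem relative to the liner rim.  The
    femoral diaphysis is not meshed: the liner rim circle lies one head
    radius from the origin and cannot reach it.
    """
    if resolution < 16:
        raise ValueError("mesh resolution must be >= 16 segments/revolution")
    if head.offset_mm not in stem.supported_offsets_mm:
        raise ValueError(
            f"offset {head.offset_mm} not in supported {stem.supported_offsets_mm}"
        )
    prof = stem.neck
    m, e_ap, e_pd = neck_frame(stem.neck_shaft_angle_deg)
    s_tip = prof.trunnion_tip_offset_mm + head.offset_mm
    psis = np.linspace(0.0, 2 * np.pi, resolution, endpoint=False)
    dirs = np.cos(psis)[:, None] * e_ap + np.sin(psis)[:, None] * e_pd

    spacing = 2 * np.pi * (prof.trunnion_diameter_mm / 2.0) / resolution
    rings = []

    def add_ring(sigma: float, radii: np.ndarray):
        center = (s_tip + sigma) * m
        rings.append(center + radii[:, None] * dirs)

    n_tr = max(3, int(np.ceil(prof.trunnion_length_mm / spacing)))
    for sg in np.linspace(0.0, prof.trunnion_length_mm, n_tr + 1):
        add_ring(sg, np.full(resolution, float(prof.trunnion_radius(sg))))

    n_nk = max(6, int(np.ceil(prof.neck_length_mm / spacing)))
    stations = np.linspace(
        prof.trunnion_length_mm, prof.total_length_mm, n_nk + 1
    )
    for sg in stations:
        h_ap, h_pd = prof.half_widths(sg)
        radii = _rounded_rect_radius(
            psis, float(h_ap), float(h_pd), prof.corner_radius_mm
        )
        # skip a duplicate junction ring when the neck section matches the
        # trunnion circle (cylindrical profile: no step)
        if sg == stations[0] and np.allclose(
            radii, prof.trunnion_radius(sg), atol=1e-9
        ):
            continue
        add_ring(sg, radii)

    mesh = _tube_mesh(rings)
    if not mesh.is_watertight:
        raise RuntimeError("generated stem mesh is not watertight")
    return mesh


def liner_profile_2d(liner: LinerSpec,
                     resolution: int = DEFAULT_RESOLUTION) -> np.ndarray:
    """Meridian polyline of the liner solid in (radial, axial) coordinates.

    Axial coordinate is along the cup axis with the cavity centre at 0 and
    the opening toward +.  The polyline starts and ends on the axis so a
    full revolution closes the solid; the same polyline (closed along the
    axis) is the exact cross-section polygon of the revolved mesh.
    """
    R = liner.inner_radius_mm
    w_rim = liner.rim_plane_mm
    r_out = liner.rim_outer_radius_mm
    w_bot = -R - 3.0
    phi = np.arccos(np.clip(-w_rim / R, -1.0, 1.0))  # polar angle from the pole
    n_arc = max(8, resolution // 2)
    t = np.linspace(phi, 0.0, n_arc + 1)
    arc = np.column_stack([R * np.sin(t), -R * np.cos(t)])
    pts = np.vstack(
        [
            [0.0, w_bot],
            [r_out, w_bot],
            [r_out, w_rim],
            [liner.rim_radius_mm, w_rim],
            arc,
        ]
    )
    return pts


def make_liner_mesh(liner: LinerSpec,
                    resolution: int = DEFAULT_RESOLUTION) -> trimesh.Trimesh:
    """Watertight liner mesh: revolved meridian profile, cavity centre at
    the origin, opening along local +Z."""
    if resolution < 16:
        raise ValueError("mesh resolution must be >= 16 segments/revolution")
    pts = liner_profile_2d(liner, resolution)
    mesh = trimesh.creation.revolve(pts, sections=resolution)
    if mesh.volume < 0:
        mesh.invert()
    if not mesh.is_watertight:
        raise RuntimeError("generated liner mesh is not watertight")
    return mesh


@dataclass
class ImplantAssembly:
    """Stem + head + liner with meshes, head centre at the origin."""

    stem: StemSpec
    head: HeadSpec
    liner: LinerSpec
    stem_mesh: trimesh.Trimesh = field(repr=False)
    liner_mesh: trimesh.Trimesh = field(repr=False)
    resolution: int = DEFAULT_RESOLUTION

    def __post_init__(self):
        m, e_ap, e_pd = neck_frame(self.stem.neck_shaft_angle_deg)
        self.neck_axis_distal = m
        self.neck_axis_head = -m
        self.e_ap = e_ap
        self.e_pd = e_pd
        self.s_tip = self.stem.neck.trunnion_tip_offset_mm + self.head.offset_mm

    def parameter_hash(self) -> str:
        payload = {
            "stem": asdict(self.stem),
            "head": asdict(self.head),
            "liner": asdict(self.liner),
            "resolution": self.resolution,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]

    def width_range(self) -> tuple[float, float]:
        return self.stem.neck.width_range()

    def station_of(self, point) -> float:
        """Neck station sigma (from the trunnion tip) of an assembly-frame point."""
        return float(np.dot(np.asarray(point), self.neck_axis_distal) - self.s_tip)


def neck_width_at_contact(assembly: ImplantAssembly, point) -> tuple[float, str]:
    """Neck width n (mm) governing impingement at a contact point.

    Convention: n is twice the perpendicular distance from the contact point
    to the neck axis (the line through the head centre along the neck).  For
    a contact on the liner rim — which lies on the cavity sphere of radius r
    — this is exactly the chord entering ``sin(gamma) = n / (2 r)`` in the
    cone-overlap formula, and it reduces to the section diameter for
    cylindrical necks.  The returned site flag is ``"trunnion"`` when the
    contact station lies on (or proximal to) the trunnion frustum.
    """
    p = np.asarray(point, dtype=float)
    m = assembly.neck_axis_distal
    axial = np.dot(p, m)
    n = 2.0 * float(np.linalg.norm(p - axial * m))
    sigma = axial - assembly.s_tip
    site = SITE_TRUNNION if sigma <= assembly.stem.neck.trunnion_length_mm else SITE_NECK
    return n, site


def export_meshes(assembly: ImplantAssembly, out_dir, fmt: str = "stl"):
    """Write the stem and liner meshes as STL (binary) or OBJ files."""
    from pathlib import Path

    if fmt not in ("stl", "obj"):
        raise ValueError("mesh format must be 'stl' or 'obj'")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, mesh in (("stem", assembly.stem_mesh), ("liner", assembly.liner_mesh)):
        path = out / f"{name}.{fmt}"
        mesh.export(path)
        paths.append(path)
    return paths


def make_assembly(stem: StemSpec, head: HeadSpec, liner: LinerSpec,
                  resolution: int = DEFAULT_RESOLUTION) -> ImplantAssembly:
    """Build meshes and assemble; validates head/liner congruence."""
    if abs(head.radius_mm - liner.inner_radius_mm) > 1e-9:
        raise ValueError("head radius must equal the liner inner radius")
    stem_mesh = make_stem_mesh(stem, head, resolution)
    liner_mesh = make_liner_mesh(liner, resolution)
    return ImplantAssembly(
        stem=stem, head=head, liner=liner,
        stem_mesh=stem_mesh, liner_mesh=liner_mesh, resolution=resolution,
    )
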