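"""Parametric implant geometry: meshes, profiles and width conventions."""

import numpy as np
import pytest

from hiprom.implants import (
    HeadSpec,
    LinerSpec,
    NeckProfile,
    StemSpec,
    liner_profile_2d,
    make_liner_mesh,
    make_stem_mesh,
    neck_width_at_contact,
)
from hiprom.fixtures import hemispherical_liner, trapezoidal_stem


def test_meshes_watertight_positive_volume(cylindrical, trapezoidal):
    for a in (cylindrical, trapezoidal):
        assert a.stem_mesh.is_watertight and a.stem_mesh.volume > 0
        assert a.liner_mesh.is_watertight and a.liner_mesh.volume > 0


def test_hemispherical_liner_volume_matches_closed_form():
    """Revolved liner volume = outer cylinder minus the spherical cap."""
    r = 16.0
    liner = hemispherical_liner(r)
    mesh = make_liner_mesh(liner, resolution=64)
    prof = liner_profile_2d(liner, 64)
    w_rim, w_bot = liner.rim_plane_mm, prof[0, 1]
    d = liner.depth_mm
    expected = (
        np.pi * liner.rim_outer_radius_mm**2 * (w_rim - w_bot)
        - np.pi * d * d * (3 * r - d) / 3.0
    )
    assert abs(mesh.volume - expected) / expected < 0.01


def test_lipped_liner_rim_beyond_centre():
    liner = LinerSpec(inner_radius_mm=16.0, depth_mm=18.0)
    assert liner.rim_plane_mm == pytest.approx(2.0)
    hemi = LinerSpec(inner_radius_mm=16.0, depth_mm=16.0)
    assert hemi.rim_plane_mm == pytest.approx(0.0)
    with pytest.raises(ValueError):
        LinerSpec(inner_radius_mm=16.0, depth_mm=33.0)


def test_cylindrical_profile_constant_width():
    prof = NeckProfile.cylindrical(12.0)
    sig = np.linspace(0.0, prof.total_length_mm, 50)
    ap, pd = prof.width_fn(sig)
    assert np.allclose(ap, 12.0) and np.allclose(pd, 12.0)


def test_trapezoidal_profile_monotone_and_trunnion_step():
    prof = trapezoidal_stem().neck
    sig = np.linspace(prof.trunnion_length_mm + 0.1, prof.total_length_mm, 40)
    _, pd = prof.width_fn(sig)
    assert np.all(np.diff(pd) > 0), "PD width widens toward the neck base"
    # trunnion wider than the neck at the junction
    assert prof.trunnion_diameter_mm > prof.pd_width_junction_mm


@pytest.mark.parametrize("station_frac", [0.3, 0.7])
def test_mesh_section_width_matches_width_fn(trapezoidal, station_frac):
    """Slicing the stem mesh at a neck station reproduces the analytic
    widths to within one mesh edge length."""
    a = trapezoidal
    prof = a.stem.neck
    sigma = prof.trunnion_length_mm + station_frac * prof.neck_length_mm
    origin = (a.s_tip + sigma) * a.neck_axis_distal
    section = a.stem_mesh.section(
        plane_origin=origin, plane_normal=a.neck_axis_distal
    )
    assert section is not None
    pts = section.vertices - origin
    ap = pts @ a.e_ap
    pd = pts @ a.e_pd
    edge = float(a.stem_mesh.edges_unique_length.mean())
    h_ap, h_pd = prof.half_widths(sigma)
    assert abs((ap.max() - ap.min()) - 2 * h_ap) < edge
    assert abs((pd.max() - pd.min()) - 2 * h_pd) < edge


def test_neck_width_at_contact_conventions(cylindrical, trapezoidal):
    # cylindrical: any surface point measures the constant diameter
    a = cylindrical
    prof = a.stem.neck
    sigma = prof.trunnion_length_mm + 10.0
    p = (a.s_tip + sigma) * a.neck_axis_distal + 6.0 * a.e_ap
    n, site = neck_width_at_contact(a, p)
    assert n == pytest.approx(12.0)
    assert site == "neck"

    # trunnion-level contact is flagged
    t = trapezoidal
    p_tr = (t.s_tip + 1.0) * t.neck_axis_distal + 7.0 * t.e_pd
    _, site_tr = neck_width_at_contact(t, p_tr)
    assert site_tr == "trunnion"

    # trapezoidal: widths at two stations differ, both within profile range
    lo, hi = t.width_range()
    widths = []
    for sg in (8.0, 20.0):
        h_ap, _ = t.stem.neck.half_widths(sg)
        p = (t.s_tip + sg) * t.neck_axis_distal + float(h_ap) * t.e_ap
        w, _ = neck_width_at_contact(t, p)
        widths.append(w)
    assert abs(widths[0] - widths[1]) > 0.5
    assert all(lo - 1e-6 <= w <= hi + 1e-6 for w in widths)


def test_offset_moves_stem_relative_to_head_centre():
    """Longer head offsets push the trunnion tip further from the rotation
    centre, so the rim meets more distal (narrower) neck stations."""
    stem = trapezoidal_stem()
    tips = []
    for off in (-4.0, 0.0, 4.0, 8.0):
        mesh = make_stem_mesh(stem, HeadSpec(16.0, offset_mm=off))
        axial = np.asarray(mesh.vertices) @ np.array(
            [np.cos(np.radians(35.0)), 0.0, -np.sin(np.radians(35.0))]
        )
        tips.append(axial.min())
    assert np.all(np.diff(tips) > 0)


def test_invalid_inputs_rejected():
    with pytest.raises(ValueError):
        HeadSpec(radius_mm=-1.0)
    with pytest.raises(ValueError):
        StemSpec(neck=NeckProfile.cylindrical(12.0), neck_shaft_angle_deg=90.0)
    with pytest.raises(ValueError):
        make_stem_mesh(
            StemSpec(neck=NeckProfile.cylindrical(12.0)),
            HeadSpec(16.0, offset_mm=3.0),  # unsupported offset
        )
    with pytest.raises(ValueError):
        make_stem_mesh(
            StemSpec(neck=NeckProfile.cylindrical(12.0)),
            HeadSpec(16.0),
            resolution=8,
        )


def test_mesh_export_roundtrip(cylindrical, tmp_path):
    import trimesh

    from hiprom.implants import export_meshes

    for fmt in ("stl", "obj"):
        paths = export_meshes(cylindrical, tmp_path / fmt, fmt=fmt)
        assert {p.name for p in paths} == {f"stem.{fmt}", f"liner.{fmt}"}
        back = trimesh.load(paths[0])
        # binary STL stores float32 vertices: micro-level roundtrip error
        assert abs(back.volume - cylindrical.stem_mesh.volume) < 0.01
    with pytest.raises(ValueError):
        export_meshes(cylindrical, tmp_path, fmt="ply3")
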