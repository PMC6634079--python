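"""Cone-overlap ROM formula and boundary solving."""

import numpy as np
import pytest
from scipy.optimize import brentq

from hiprom.fixtures import hemispherical_liner
from hiprom.implants import HeadSpec, LinerSpec
from hiprom.kinematics import (
    SHAFT_AXIS,
    CupOrientation,
    JointMotion,
    StemPose,
    cup_axis,
    motion_path,
    motion_rotation,
)
from hiprom.neckwidth import EXTENSION_SIDE, FLEXION_SIDE
from hiprom.rom import (
    GeometricInfeasibilityError,
    ROMTarget,
    SENTINEL_DEG,
    achieved_rom,
    cone_half_angles,
    max_secondary_rotation,
    solve_boundary,
)

HEAD = HeadSpec(16.0)
LINER = hemispherical_liner(16.0)


def _neck_axis():
    from hiprom.implants import neck_frame

    return neck_frame(125.0)[0]


def test_cone_half_angles_closed_form():
    phi, gamma = cone_half_angles(HEAD, LINER, 10.0)
    assert phi == pytest.approx(90.0)
    assert gamma == pytest.approx(np.degrees(np.arcsin(10.0 / 32.0)))
    # allowed tilt of the neck axis from the cup normal
    assert phi - gamma == pytest.approx(
        90.0 - np.degrees(np.arcsin(10.0 / 32.0)), abs=1e-6
    )
    # a shallow liner's rim sits past the equator: more clearance
    shallow = LinerSpec(inner_radius_mm=16.0, depth_mm=12.0)
    phi_s, _ = cone_half_angles(HEAD, shallow, 10.0)
    assert phi_s > 90.0


def test_infeasible_geometry_raises():
    deep_lip = LinerSpec(inner_radius_mm=16.0, depth_mm=31.5)
    with pytest.raises(GeometricInfeasibilityError):
        cone_half_angles(HEAD, deep_lip, 14.0)
    with pytest.raises(ValueError):
        cone_half_angles(HEAD, LINER, 40.0)  # wider than the head


def _brute_max_secondary(cup, pose, n, primary, secondary_kind):
    """Independent oracle: fine scan + Brent on the angle-to-axis function,
    composing rotations step by step with scipy only."""
    phi, gamma = cone_half_angles(HEAD, LINER, n)
    limit = phi - gamma
    u = cup_axis(cup.inclination_deg, cup.anteversion_deg)
    m0 = _neck_axis()

    def angle_at(theta):
        motion = JointMotion(primary[0], primary[1], secondary_kind, theta)
        m = motion_rotation(pose, motion).apply(m0)
        return np.degrees(np.arccos(np.clip(np.dot(m, u), -1, 1))) - limit

    if angle_at(0.0) > 0:
        return 0.0
    thetas = np.arange(0.0, SENTINEL_DEG + 0.1, 0.1)
    vals = np.array([angle_at(t) for t in thetas])
    idx = np.flatnonzero(vals > 0)
    if len(idx) == 0:
        return SENTINEL_DEG
    k = idx[0]
    return brentq(angle_at, thetas[k - 1], thetas[k], xtol=1e-8)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_closed_form_exit_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    m0 = _neck_axis()
    for _ in range(5):
        cup = CupOrientation(rng.uniform(20, 60), rng.uniform(0, 40))
        pose = StemPose(anteversion_deg=rng.uniform(-20, 40))
        n = rng.uniform(10.0, 16.0)
        primary = ("flexion", rng.uniform(0, 100))
        got = max_secondary_rotation(
            cup, pose, HEAD, LINER, n, m0, primary, "internal_rotation",
            path_step_deg=0.5,
        )
        expected = _brute_max_secondary(cup, pose, n, primary, "internal_rotation")
        if expected in (0.0, SENTINEL_DEG):
            assert got == pytest.approx(expected, abs=0.6)
        else:
            assert got == pytest.approx(expected, abs=1e-4)


def test_limit_monotonicities():
    """IR limit falls with neck width, rises with head radius at fixed n,
    falls with liner depth beyond the hemisphere."""
    m0 = _neck_axis()
    cup = CupOrientation(45.0, 20.0)
    pose = StemPose(anteversion_deg=15.0)
    primary = ("flexion", 90.0)

    def limit(head=HEAD, liner=LINER, n=12.0):
        return max_secondary_rotation(
            cup, pose, head, liner, n, m0, primary, "internal_rotation"
        )

    assert limit(n=10.0) > limit(n=14.0)  # constant-width necks lose ROM as n grows
    big = HeadSpec(20.0)
    assert limit(head=big, liner=hemispherical_liner(20.0), n=12.0) > limit(n=12.0)
    lipped = LinerSpec(inner_radius_mm=16.0, depth_mm=19.0)
    assert limit(liner=lipped) < limit()


def test_sentinel_and_primary_violation():
    m0 = _neck_axis()
    pose = StemPose(anteversion_deg=0.0, adduction_deg=0.0)
    # cup opening straight inferior: axial rotation sweeps the neck on a
    # cone at a constant 55 deg from the cup axis, never reaching the limit
    aligned = max_secondary_rotation(
        CupOrientation(0.0, 0.0), pose, HEAD, LINER, 4.0, m0,
        ("flexion", 0.0), "internal_rotation",
    )
    assert aligned == SENTINEL_DEG
    # cup facing far from the neck: the primary motion alone violates
    violated = max_secondary_rotation(
        CupOrientation(0.0, 50.0), pose, HEAD, LINER, 12.0, m0,
        ("flexion", 90.0), "internal_rotation",
    )
    assert violated == 0.0


def test_achieved_rom_db_matches_constant_for_cylinder(cylindrical, cylindrical_db, target30):
    pose = StemPose(anteversion_deg=15.0)
    cup = CupOrientation(45.0, 20.0)
    via_db = achieved_rom(
        cup, pose, cylindrical.head, cylindrical.liner, cylindrical_db,
        target30, cylindrical.neck_axis_distal,
    )
    via_const = achieved_rom(
        cup, pose, cylindrical.head, cylindrical.liner, 12.0,
        target30, cylindrical.neck_axis_distal,
    )
    assert via_db[0] == pytest.approx(via_const[0], abs=0.1)
    assert via_db[1] == pytest.approx(via_const[1], abs=0.1)


def test_flexion_satisfaction_monotone_in_anteversion(target30):
    """At alpha = 45 the achieved IR at 90 deg flexion grows with cup
    anteversion: one unsatisfied-to-satisfied transition."""
    m0 = _neck_axis()
    pose = StemPose(anteversion_deg=15.0)
    betas = np.arange(0.0, 45.0, 2.5)
    achieved = [
        max_secondary_rotation(
            CupOrientation(45.0, b), pose, HEAD, LINER, 12.0, m0,
            ("flexion", 90.0), "internal_rotation",
        )
        for b in betas
    ]
    sat = np.array(achieved) >= 30.0
    flips = np.flatnonzero(np.diff(sat.astype(int)))
    assert len(flips) == 1 and sat[-1]


def test_boundary_matches_independent_scan(target30):
    """Constant-n boundary equals the crossing of the brute-force achieved
    curve to within the solver tolerance."""
    m0 = _neck_axis()
    pose = StemPose(anteversion_deg=15.0)
    bd = solve_boundary(
        target30, pose, HEAD, LINER, 12.0, FLEXION_SIDE, [45.0], m0
    )
    assert len(bd.points) == 1
    beta_solved = bd.points[0][1]

    def g(beta):
        return (
            _brute_max_secondary(
                CupOrientation(45.0, beta), pose, 12.0, ("flexion", 90.0),
                "internal_rotation",
            )
            - 30.0
        )

    beta_ref = brentq(g, 0.0, 60.0, xtol=1e-6)
    assert beta_solved == pytest.approx(beta_ref, abs=0.05)


def test_boundary_shifts_down_with_stem_anteversion(target30):
    """Higher stem anteversion pairs with lower cup anteversion."""
    m0 = _neck_axis()
    betas = []
    for b in (-10.0, 0.0, 10.0):
        bd = solve_boundary(
            target30, StemPose(anteversion_deg=b), HEAD, LINER, 12.0,
            FLEXION_SIDE, [45.0], m0,
        )
        assert bd.points
        betas.append(bd.points[0][1])
    assert betas[0] > betas[1] > betas[2]


def test_extension_boundary_present_and_decreasing_side(target30):
    m0 = _neck_axis()
    bd = solve_boundary(
        target30, StemPose(anteversion_deg=10.0), HEAD, LINER, 12.0,
        EXTENSION_SIDE, [40.0, 50.0], m0,
    )
    assert bd.points
    for alpha, beta in bd.points:
        lo = achieved_rom(
            CupOrientation(alpha, beta - 2.0), StemPose(10.0), HEAD, LINER,
            12.0, target30, m0,
        )[1]
        hi = achieved_rom(
            CupOrientation(alpha, beta + 2.0), StemPose(10.0), HEAD, LINER,
            12.0, target30, m0,
        )[1]
        assert lo >= 10.0 >= hi


def test_target_parsing_semantics():
    t = ROMTarget(45.0, 90.0, 10.0, 30.0)
    m = t.motion(FLEXION_SIDE)
    assert (m.primary, m.primary_deg, m.secondary, m.secondary_deg) == (
        "flexion", 90.0, "internal_rotation", 45.0,
    )
    m = t.motion(EXTENSION_SIDE)
    assert (m.primary, m.primary_deg, m.secondary, m.secondary_deg) == (
        "extension", 30.0, "external_rotation", 10.0,
    )
    with pytest.raises(ValueError):
        ROMTarget(-1.0, 90.0, 10.0, 10.0)
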