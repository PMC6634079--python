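"""Frames, the radiographic cup convention and motion composition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hiprom.kinematics import (
    CupOrientation,
    JointMotion,
    StemPose,
    cup_angles,
    cup_axis,
    motion_path,
    motion_rotation,
    pose_rotation,
    stem_neck_axis,
)
from hiprom.implants import neck_frame

angles = st.floats(min_value=0.0, max_value=60.0)
anteversions = st.floats(min_value=-40.0, max_value=60.0)


def test_cup_axis_anchors():
    assert np.allclose(cup_axis(0.0, 0.0), [0.0, 0.0, -1.0])
    assert np.allclose(cup_axis(90.0, 0.0), [1.0, 0.0, 0.0])
    # anteversion tips the opening anteriorly
    assert cup_axis(45.0, 20.0)[1] > 0


@given(a=angles, b=anteversions)
@settings(max_examples=200, deadline=None)
def test_cup_axis_roundtrip(a, b):
    alpha, beta = cup_angles(cup_axis(a, b))
    assert abs(alpha - a) < 1e-9 or a == 0.0  # alpha degenerate only at poles
    assert abs(beta - b) < 1e-9


@given(
    b=st.floats(-40, 60), add=st.floats(0, 10), fl=st.floats(0, 120),
    sec=st.floats(0, 170),
)
@settings(max_examples=100, deadline=None)
def test_rotations_preserve_norm(b, add, fl, sec):
    pose = StemPose(anteversion_deg=b, adduction_deg=add)
    motion = JointMotion("flexion", fl, "internal_rotation", sec)
    m, _, _ = neck_frame(125.0)
    v = motion_rotation(pose, motion).apply(m)
    assert abs(np.linalg.norm(v) - 1.0) < 1e-12


def test_neutral_neck_axis_elevation():
    """Neck-shaft angle 125 deg puts the neck 35 deg above the transverse
    plane, in the coronal plane, pointing medial-superior."""
    m, _, _ = neck_frame(125.0)
    u_head = -m
    assert u_head[1] == pytest.approx(0.0)
    elevation = np.degrees(np.arcsin(u_head[2]))
    assert elevation == pytest.approx(35.0)
    assert u_head[0] < 0  # medial


def test_stem_anteversion_moves_neck_anteriorly():
    m, _, _ = neck_frame(125.0)
    u0 = stem_neck_axis(StemPose(0.0, 0.0), -m, JointMotion())
    u20 = stem_neck_axis(StemPose(20.0, 0.0), -m, JointMotion())
    assert u0[1] == pytest.approx(0.0, abs=1e-12)
    assert u20[1] > 0.05


def test_axial_rotation_sweeps_cone_about_shaft():
    """With a vertical shaft, axial rotation keeps the neck's elevation."""
    m, _, _ = neck_frame(125.0)
    elev = []
    for b in (0.0, 30.0, 60.0, 90.0):
        u = stem_neck_axis(StemPose(b, 0.0), -m, JointMotion())
        elev.append(np.degrees(np.arcsin(u[2])))
    assert np.allclose(elev, 35.0, atol=1e-9)


def test_motion_order_not_commutative():
    """With the flexion axis and the (flexed) shaft axis both held fixed,
    swapping the application order changes the neck axis: the composition
    order flexion-then-rotation is load-bearing."""
    from hiprom.kinematics import _rot, primary_rotation, SHAFT_AXIS

    pose = StemPose(anteversion_deg=15.0)
    m, _, _ = neck_frame(125.0)
    base = pose_rotation(pose)
    r_flex = primary_rotation("flexion", 90.0)
    shaft_flexed = (r_flex * base).apply(SHAFT_AXIS)
    r_ir = _rot(shaft_flexed, 30.0)
    ordered = (r_ir * r_flex * base).apply(m)
    swapped = (r_flex * r_ir * base).apply(m)
    assert np.linalg.norm(ordered - swapped) > 0.05
    # and this is exactly what motion_rotation computes
    direct = motion_rotation(
        pose, JointMotion("flexion", 90.0, "internal_rotation", 30.0)
    ).apply(m)
    assert np.allclose(ordered, direct, atol=1e-12)


def _quat_mul(q, r):
    w1, x1, y1, z1 = q
    w2, x2, y2, z2 = r
    return np.array(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ]
    )


def _quat_about(axis, deg):
    h = np.radians(deg) / 2.0
    a = np.asarray(axis) / np.linalg.norm(axis)
    return np.concatenate([[np.cos(h)], np.sin(h) * a])


def _quat_apply(q, v):
    qv = np.concatenate([[0.0], v])
    w, x, y, z = _quat_mul(_quat_mul(q, qv), q * np.array([1, -1, -1, -1]))
    return np.array([x, y, z])


def test_composition_matches_independent_quaternion_implementation():
    """(a=125, b=15, adduction=6, FL=90, IR=30) via hand-rolled quaternions."""
    m, _, _ = neck_frame(125.0)
    pose = StemPose(anteversion_deg=15.0, adduction_deg=6.0)
    motion = JointMotion("flexion", 90.0, "internal_rotation", 30.0)
    got = stem_neck_axis(pose, -m, motion)

    X, Y, Z = np.eye(3)
    q = _quat_about(Y, 6.0)  # adduction
    shaft = _quat_apply(q, Z)
    q = _quat_mul(_quat_about(shaft, -15.0), q)  # anteversion
    q = _quat_mul(_quat_about(X, 90.0), q)  # flexion
    shaft = _quat_apply(q, Z)
    q = _quat_mul(_quat_about(shaft, 30.0), q)  # internal rotation
    expected = _quat_apply(q, -m)
    assert np.allclose(got, expected, atol=1e-12)


def test_motion_path_end_matches_direct_rotation():
    pose = StemPose(anteversion_deg=-10.0)
    motion = JointMotion("extension", 10.0, "external_rotation", 25.0)
    path = motion_path(pose, motion, step_deg=2.0)
    direct = motion_rotation(pose, motion).as_matrix()
    assert np.allclose(path.matrices[-1], direct, atol=1e-12)
    assert np.allclose(
        path.secondary_matrix(motion.secondary_deg), direct, atol=1e-12
    )


def test_invalid_motions_rejected():
    with pytest.raises(ValueError):
        JointMotion("circumduction", 10.0, "internal_rotation", 5.0)
    with pytest.raises(ValueError):
        JointMotion("flexion", -5.0, "internal_rotation", 5.0)
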