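"""Landmark frame, chart coordinates and rigid landmark registration."""

import numpy as np
import pytest
import trimesh
from scipy.spatial.transform import Rotation

import bonemap as bm
from bonemap.errors import ValidationError


@pytest.fixture()
def unit_frame():
    return bm.LandmarkFrame(hs=[0, 0, 0], zl_a=[0, 0, 0], zl_b=[1, 0, 0],
                            cranial_ref=[0, 1, 0])


def test_frame_validation():
    with pytest.raises(ValidationError):
        bm.LandmarkFrame(hs=[0, 0, 0], zl_a=[1, 1, 1], zl_b=[1, 1, 1],
                         cranial_ref=[0, 1, 0])
    with pytest.raises(ValidationError):
        bm.LandmarkFrame(hs=[0, 0, 0], zl_a=[0, 0, 0], zl_b=[1, 0, 0],
                         cranial_ref=[0, 1, 0], sphere_interval=0.0)


def test_hs_maps_to_chart_origin(unit_frame):
    assert bm.hs_zl_coordinates(unit_frame.hs, unit_frame) == pytest.approx((0.0, 0.0))


def test_point_on_zl_line_has_zero_cranial_component(unit_frame):
    assert bm.hs_zl_coordinates([20.0, 0.0, 0.0], unit_frame) == \
        pytest.approx((20.0, 0.0))


def test_known_analytic_chart_coordinates(unit_frame):
    assert bm.hs_zl_coordinates([45.0, 16.0, 0.0], unit_frame) == \
        pytest.approx((45.0, 16.0))


def test_chart_invariant_under_common_rigid_motion(unit_frame):
    rng = np.random.default_rng(11)
    point = np.array([33.0, 12.0, -4.0])
    ref = bm.hs_zl_coordinates(point, unit_frame)
    for _ in range(20):
        R = Rotation.random(random_state=int(rng.integers(2 ** 31))).as_matrix()
        t = rng.normal(size=3) * 50
        moved = bm.LandmarkFrame(
            hs=R @ unit_frame.hs + t, zl_a=R @ unit_frame.zl_a + t,
            zl_b=R @ unit_frame.zl_b + t, cranial_ref=R @ unit_frame.cranial_ref + t)
        assert bm.hs_zl_coordinates(R @ point + t, moved) == pytest.approx(ref, abs=1e-9)


def test_chart_equivariant_along_zl_direction(unit_frame):
    p = np.array([10.0, 5.0, 2.0])
    post0, cran0 = bm.hs_zl_coordinates(p, unit_frame)
    post1, cran1 = bm.hs_zl_coordinates(p + 7.5 * unit_frame.zl_direction, unit_frame)
    assert post1 - post0 == pytest.approx(7.5)
    assert cran1 == pytest.approx(cran0)


def test_degenerate_cranial_reference_rejected():
    frame = bm.LandmarkFrame(hs=[0, 0, 0], zl_a=[0, 0, 0], zl_b=[1, 0, 0],
                             cranial_ref=[5, 0, 0])  # on the ZL axis
    with pytest.raises(ValidationError, match="degenerate"):
        bm.hs_zl_coordinates([1.0, 2.0, 3.0], frame)


def test_overlay_rings_and_line(unit_frame):
    mesh = trimesh.Trimesh(
        vertices=[[0, 0, 0], [10, 0, 0], [7.3, 2.0, 0], [3, 0.2, 0]],
        faces=[[0, 1, 2], [0, 2, 3]], process=False)
    ch = bm.build_frame_overlays(unit_frame, mesh)
    assert ch["hs_ring"].tolist() == [1, 1, 0, 0]   # 0 and 10 are multiples of 5
    assert ch["zl_line"].tolist() == [1, 1, 0, 1]   # within 0.5 mm of the x-axis


def test_sphere_mesh_ring_flags_all_or_none():
    frame = bm.LandmarkFrame(hs=[0, 0, 0], zl_a=[0, 0, 0], zl_b=[1, 0, 0],
                             cranial_ref=[0, 0, 1], sphere_interval=5.0)
    on = trimesh.creation.icosphere(2, radius=10.0)      # on a ring
    off = trimesh.creation.icosphere(2, radius=7.5)      # between rings
    assert bm.build_frame_overlays(frame, on)["hs_ring"].all()
    assert not bm.build_frame_overlays(frame, off)["hs_ring"].any()


def test_registration_identity():
    src = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0], [3, 4, 5]], float)
    tf, res = bm.rigid_landmark_register(src, src)
    np.testing.assert_allclose(tf.rotation, np.eye(3), atol=1e-12)
    np.testing.assert_allclose(tf.translation, 0, atol=1e-12)
    assert res.max() < 1e-12


def test_registration_recovers_known_transform():
    src = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0], [3, 4, 5]], float)
    R = Rotation.from_euler("z", 30, degrees=True).as_matrix()
    t = np.array([1.0, 2.0, 3.0])
    tf, res = bm.rigid_landmark_register(src, src @ R.T + t)
    np.testing.assert_allclose(tf.rotation, R, atol=1e-9)
    np.testing.assert_allclose(tf.translation, t, atol=1e-9)
    assert res.max() < 1e-9


def test_registration_matches_independent_solver():
    """Cross-check the closed-form fit against scipy's Wahba solver."""
    rng = np.random.default_rng(5)
    src = rng.normal(size=(6, 3)) * 30
    tgt = src @ Rotation.random(random_state=1).as_matrix().T + [4, -2, 9] \
        + rng.normal(size=(6, 3)) * 0.2
    tf, _ = bm.rigid_landmark_register(src, tgt)
    rot, _ = Rotation.align_vectors(tgt - tgt.mean(0), src - src.mean(0))
    np.testing.assert_allclose(tf.rotation, rot.as_matrix(), atol=1e-9)


def test_registration_never_returns_reflection():
    src = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10]], float)
    tgt = src * np.array([1, 1, -1])     # a mirror fits perfectly; rotation must not
    tf, res = bm.rigid_landmark_register(src, tgt)
    assert np.linalg.det(tf.rotation) == pytest.approx(1.0)
    assert res.max() > 1.0               # honest residual instead of a reflection


def test_noisy_landmarks_small_mean_residual():
    rng = np.random.default_rng(2026)
    src = np.array([[0, 0, 0], [30, 0, 0], [0, 30, 0], [10, 10, 20]], float)
    residuals = []
    for _ in range(100):
        R = Rotation.random(random_state=int(rng.integers(2 ** 31))).as_matrix()
        t = rng.normal(size=3) * 20
        tgt = src @ R.T + t + rng.normal(size=src.shape) * 0.1
        _, res = bm.rigid_landmark_register(src, tgt)
        residuals.append(res.mean())
    assert np.mean(residuals) <= 0.3


@pytest.mark.parametrize("src,tgt,msg", [
    (np.zeros((2, 3)), np.zeros((2, 3)), "at least 3"),
    (np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], float),
     np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], float), "collinear"),
])
def test_registration_input_validation(src, tgt, msg):
    with pytest.raises(ValidationError, match=msg):
        bm.rigid_landmark_register(src, tgt)


def test_landmark_sidecar_roundtrip(tmp_path, unit_frame):
    path = bm.write_landmarks(unit_frame, tmp_path / "lm.json")
    back = bm.read_landmarks(path)
    np.testing.assert_allclose(back.hs, unit_frame.hs)
    np.testing.assert_allclose(back.zl_b, unit_frame.zl_b)
    assert back.side == unit_frame.side


def test_measure_port_position_delegates_to_chart(unit_frame):
    rec = bm.measure_port_position([45.0, 16.0, 0.0], unit_frame)
    assert rec["posterior_mm"] == pytest.approx(45.0)
    assert rec["cranial_mm"] == pytest.approx(16.0)
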