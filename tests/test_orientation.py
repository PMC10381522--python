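import numpy as np
import pytest

from enamelmap import (SurfaceMesh, apply_frame, classify_surfaces,
                       frame_from_cervical_edge, refine_frame_with_occlusal)
from enamelmap.cap_segmentation import Contour3D
from enamelmap.errors import DegenerateEdgeError, InsufficientContourError
from enamelmap.orientation import ToothFrame

from conftest import random_rotation


def circle_contour(radius=8.0, center=(3.0, 4.0, 5.0), n=100):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack([center[0] + radius * np.cos(th),
                           center[1] + radius * np.sin(th),
                           np.full(n, center[2])])
    return Contour3D(pts, closed=True)


def ellipse_contour(a=9.5, b=8.3, angle_deg=30.0, n=200):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts2 = np.column_stack([a * np.cos(th), b * np.sin(th)])
    ang = np.radians(angle_deg)
    R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    pts2 = pts2 @ R.T
    return Contour3D(np.column_stack([pts2, np.zeros(n)]), closed=True)


class TestFrameFromCervicalEdge:
    def test_planar_circle(self):
        frame = frame_from_cervical_edge(circle_contour())
        assert np.allclose(frame.origin, [3.0, 4.0, 5.0], atol=1e-9)
        assert abs(frame.z_axis[2]) == pytest.approx(1.0, abs=1e-9)

    def test_rotated_ellipse_major_axis(self):
        frame = frame_from_cervical_edge(ellipse_contour(angle_deg=30.0))
        expected = np.array([np.cos(np.radians(30)), np.sin(np.radians(30)), 0.0])
        assert abs(np.dot(frame.x_axis, expected)) == pytest.approx(1.0,
                                                                    abs=1e-6)

    def test_collinear_edge_rejected(self):
        pts = np.column_stack([np.linspace(0, 1, 20), np.zeros(20),
                               np.zeros(20)])
        with pytest.raises(DegenerateEdgeError):
            frame_from_cervical_edge(Contour3D(pts, closed=False))

    def test_orthonormal_right_handed(self):
        frame = frame_from_cervical_edge(ellipse_contour())
        R = frame.rotation
        assert np.allclose(R @ R.T, np.eye(3), atol=1e-9)
        assert np.dot(np.cross(frame.x_axis, frame.y_axis),
                      frame.z_axis) == pytest.approx(1.0, abs=1e-9)

    def test_idempotent_after_applying(self):
        contour = ellipse_contour(angle_deg=47.0)
        frame = frame_from_cervical_edge(contour)
        moved = Contour3D(frame.to_frame(contour.points), closed=True)
        frame2 = frame_from_cervical_edge(moved)
        assert frame2.is_identity(tol=1e-6)

    def test_z_points_toward_crown(self, crown):
        cap, _ = crown
        res = classify_surfaces(cap.mesh)
        frame = frame_from_cervical_edge(res.cervical_edge, res)
        areas = res.mesh.face_areas()
        side = (res.mesh.face_centroids() - frame.origin) @ frame.z_axis
        assert areas[side > 0].sum() > areas[side < 0].sum()

    def test_rigid_motion_recovery(self, crown):
        cap, _ = crown
        base = classify_surfaces(cap.mesh)
        f0 = frame_from_cervical_edge(base.cervical_edge, base)
        canon = f0.to_frame(cap.mesh.vertices)
        R = random_rotation(5)
        moved = SurfaceMesh(cap.mesh.vertices @ R.T + [1.0, 2.0, -3.0],
                            cap.mesh.faces)
        res = classify_surfaces(moved)
        f1 = frame_from_cervical_edge(res.cervical_edge, res)
        assert np.allclose(f1.to_frame(moved.vertices), canon, atol=1e-6)


class TestRefineWithOcclusal:
    def test_coaxial_contour_is_identity(self):
        frame = frame_from_cervical_edge(ellipse_contour(angle_deg=0.0))
        occl = ellipse_contour(a=5.0, b=4.0, angle_deg=0.0)
        refined = refine_frame_with_occlusal(frame, occl)
        assert abs(np.dot(refined.x_axis, frame.x_axis)) == pytest.approx(
            1.0, abs=1e-9)

    def test_follows_rotated_contour(self):
        frame = frame_from_cervical_edge(ellipse_contour(angle_deg=0.0))
        occl = ellipse_contour(a=5.0, b=4.0, angle_deg=10.0)
        refined = refine_frame_with_occlusal(frame, occl)
        expected = np.array([np.cos(np.radians(10)), np.sin(np.radians(10)), 0])
        assert abs(np.dot(refined.x_axis, expected)) == pytest.approx(1.0,
                                                                      abs=1e-6)

    def test_mirrored_contour_keeps_right_handedness(self):
        frame = frame_from_cervical_edge(ellipse_contour(angle_deg=0.0))
        occl = ellipse_contour(a=5.0, b=4.0, angle_deg=0.0)
        mirrored = Contour3D(occl.points * [1.0, -1.0, 1.0], closed=True)
        refined = refine_frame_with_occlusal(frame, mirrored)
        assert np.dot(np.cross(refined.x_axis, refined.y_axis),
                      refined.z_axis) == pytest.approx(1.0, abs=1e-9)

    def test_short_contour_rejected(self):
        frame = ToothFrame.identity()
        pts = np.column_stack([np.cos(np.linspace(0, 5, 5)),
                               np.sin(np.linspace(0, 5, 5)), np.zeros(5)])
        with pytest.raises(InsufficientContourError):
            refine_frame_with_occlusal(frame, Contour3D(pts, closed=False))


class TestApplyFrame:
    def test_identity(self, unit_cube):
        out = apply_frame(unit_cube, ToothFrame.identity())
        assert np.allclose(out.vertices, unit_cube.vertices)

    def test_rotation_preserves_volume_and_permutes(self, unit_cube):
        frame = ToothFrame(np.zeros(3), [0, 1, 0], [-1, 0, 0], [0, 0, 1])
        out = apply_frame(unit_cube, frame)
        from enamelmap import validate
        assert validate(out).volume == pytest.approx(1.0, rel=1e-9)
        # the cube's vertex set maps onto a 90-degree rotated copy of itself
        rot = unit_cube.vertices @ frame.rotation.T
        assert np.allclose(np.sort(out.vertices, axis=0),
                           np.sort(rot, axis=0), atol=1e-12)

    def test_area_invariance(self, crown):
        cap, _ = crown
        frame = ToothFrame(np.array([1.0, -2.0, 0.5]),
                           [0.6, 0.8, 0], [-0.8, 0.6, 0], [0, 0, 1])
        out = apply_frame(cap.mesh, frame)
        assert out.area == pytest.approx(cap.mesh.area, rel=1e-9)


def test_frame_json_round_trip(tmp_path):
    frame = frame_from_cervical_edge(ellipse_contour(angle_deg=25.0))
    p = tmp_path / "frame.json"
    frame.to_json(p)
    back = ToothFrame.from_json(p)
    assert np.allclose(back.rotation, frame.rotation, atol=1e-12)
    assert np.allclose(back.origin, frame.origin, atol=1e-12)
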