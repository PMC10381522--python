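import numpy as np
import pytest
import trimesh

from enamelmap import SurfaceMesh, vertex_curvature
from enamelmap import occlusal_topography as ot
from enamelmap import synthetic_tooth as st
from enamelmap import _geometry as geom
from enamelmap.cap_segmentation import Contour3D, EnamelCap, OUTER

from conftest import parallel_plates


class TestVertexCurvature:
    def test_sphere(self):
        sph = trimesh.creation.icosphere(subdivisions=4, radius=5.0)
        field = vertex_curvature(SurfaceMesh(sph.vertices, sph.faces))
        assert np.abs(field.values / 0.2 - 1.0).max() < 0.05

    def test_flat_plate_interior(self):
        cap = parallel_plates(nx=15, ny=15)
        field = vertex_curvature(cap.mesh)
        interior = ~field.boundary
        assert interior.any()
        assert np.abs(field.values[interior]).max() < 1e-3

    def test_cylinder_interior(self):
        # open tube R=2 with interior rings: mean curvature 1/(2R) = 0.25
        R, n_theta, n_z = 2.0, 96, 41
        th = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
        zs = np.linspace(-5, 5, n_z)
        v = np.array([[R * np.cos(t), R * np.sin(t), z]
                      for z in zs for t in th])
        f = []
        for i in range(n_z - 1):
            for j in range(n_theta):
                j2 = (j + 1) % n_theta
                a, b = i * n_theta + j, i * n_theta + j2
                c, d = (i + 1) * n_theta + j, (i + 1) * n_theta + j2
                f.append([a, b, d])
                f.append([a, d, c])
        mesh = SurfaceMesh(v, np.array(f))
        field = vertex_curvature(mesh)
        interior = (np.abs(mesh.vertices[:, 2]) < 4.0) & ~field.boundary
        assert interior.any()
        vals = field.values[interior]
        assert np.abs(vals / 0.25 - 1.0).max() < 0.05

    def test_boundary_flagged(self, prismatic_band):
        cap, _ = prismatic_band
        field = vertex_curvature(cap.mesh)
        assert field.boundary.any()
        assert (field.values[field.boundary] == 0).all()


class TestOcclusalContour:
    def test_closed_loop_enclosing_apices(self, crown):
        cap, truth = crown
        contour = ot.occlusal_contour_oes(cap)
        assert contour.closed
        from shapely.geometry import Point, Polygon
        poly = Polygon(contour.points[:, :2])
        if not poly.is_valid:
            poly = poly.buffer(0)
        buffered = poly.buffer(2 * truth["resolution"])
        for apex in truth["apexes"]:
            assert buffered.contains(Point(apex[:2]))

    def test_contour_lies_on_oes_vertices(self, crown):
        cap, _ = crown
        contour = ot.occlusal_contour_oes(cap)
        oes_vertices = cap.mesh.vertices[np.unique(
            cap.mesh.faces[cap.outer_faces])]
        from scipy.spatial import cKDTree
        d, _ = cKDTree(oes_vertices).query(contour.points)
        assert d.max() < 1e-12

    def test_override_passthrough(self, crown):
        cap, truth = crown
        # analytic crest polyline: ring through both apices
        th = np.linspace(0, 2 * np.pi, 48, endpoint=False)
        ring = np.column_stack([2.2 * np.cos(th), 2.2 * np.sin(th)])
        pts = np.column_stack([ring,
                               st.crown_height(ring[:, 0], ring[:, 1],
                                               truth["spec"])])
        contour = ot.occlusal_contour_oes(cap, overrides=pts)
        # returned contour stays within one mesh-edge length of the override
        from scipy.spatial import cKDTree
        d, _ = cKDTree(pts).query(contour.points)
        assert d.max() < 2.5 * truth["resolution"]


class TestProjectToEdj:
    def test_parallel_plates_shift(self, plates):
        ys = np.linspace(0.5, 2.5, 15)
        pts = np.column_stack([np.full(15, 1.0), ys, np.full(15, 0.5)])
        contour = Contour3D(pts, closed=False)
        proj = ot.project_contour_to_edj(contour, plates)
        assert np.allclose(proj.points[:, :2], pts[:, :2], atol=1e-12)
        assert np.allclose(proj.points[:, 2], 0.0, atol=1e-9)

    def test_point_above_vertex_maps_to_it(self, plates):
        target = plates.mesh.vertices[plates.mesh.faces[
            plates.inner_faces[0]][0]]
        pts = np.tile(target + [0, 0, 0.5], (3, 1)) + \
            np.array([[0, 0, 0], [0.01, 0, 0], [0.02, 0, 0]])
        proj = ot.project_contour_to_edj(Contour3D(pts, closed=False), plates)
        assert np.allclose(proj.points[0], target, atol=1e-9)

    def test_closed_stays_closed_same_count(self, crown):
        cap, _ = crown
        contour = ot.occlusal_contour_oes(cap)
        proj = ot.project_contour_to_edj(contour, cap)
        assert proj.closed
        assert len(proj.points) == len(contour.points)


class TestSectionSeries:
    def _cube_cap(self, unit_cube):
        return EnamelCap(unit_cube, np.arange(unit_cube.n_faces),
                         np.array([], dtype=int))

    def test_cube_sections_have_unit_area(self, unit_cube):
        cap = self._cube_cap(unit_cube)
        secs = ot.section_series(cap, n=3, span="crown")
        assert [round(s.plane_x, 6) for s in secs] == [0.25, 0.5, 0.75]
        for s in secs:
            assert len(s.loops) == 1
            area = abs(geom.polygon_signed_area(s.loops[0]))
            assert area == pytest.approx(1.0, abs=1e-9)

    def test_plane_outside_is_empty(self, unit_cube):
        cap = self._cube_cap(unit_cube)
        sec = ot.PlanarSection(plane_x=5.0)
        loops = geom.plane_section_loops(unit_cube.vertices, unit_cube.faces,
                                         None, 5.0)
        assert loops == []

    def test_sectioning_conserves_volume(self, crown):
        cap, _ = crown
        secs = ot.section_series(cap, n=80, span="crown")
        x0 = cap.mesh.vertices[:, 0].min()
        x1 = cap.mesh.vertices[:, 0].max()
        dx = (x1 - x0) / 80
        total = sum(abs(geom.polygon_signed_area(loop))
                    for s in secs for loop in s.loops) * dx
        vol = abs(geom.signed_volume(cap.mesh.vertices, cap.mesh.faces))
        assert total == pytest.approx(vol, rel=0.02)

    def test_chains_partition_loop(self, crown):
        cap, _ = crown
        secs = ot.section_series(cap, n=5, span="crown")
        s = secs[2]
        n_seg = sum(len(c) for c in s.loop_classes)
        n_chain_seg = sum(len(c) - 1
                          for cls in (0, 1) for c in s.class_chains(cls))
        assert n_chain_seg == n_seg


class TestMidline:
    def test_crown_midline_on_valley(self, crown):
        cap, truth = crown
        contour = ot.occlusal_contour_oes(cap)
        secs = ot.section_series(cap, n=80, occlusal_contour=contour)
        mid = ot.midline_from_sections(secs, contour)
        assert len(mid.points) == 80
        assert np.abs(mid.points[:, 1]).max() <= 2 * truth["resolution"]

    def test_x_monotone_and_on_oes(self, crown):
        cap, _ = crown
        contour = ot.occlusal_contour_oes(cap)
        secs = ot.section_series(cap, n=40, occlusal_contour=contour)
        mid = ot.midline_from_sections(secs, contour)
        assert (np.diff(mid.points[:, 0]) > 0).all()
        oes = cap.outer_submesh()
        d, _ = geom.nearest_on_surface(mid.points, oes.vertices, oes.faces)
        assert d.max() < 1e-6

    def test_override_passthrough(self, crown):
        cap, _ = crown
        contour = ot.occlusal_contour_oes(cap)
        secs = ot.section_series(cap, n=20, occlusal_contour=contour)
        mid = ot.midline_from_sections(secs, contour,
                                       overrides={10: (0.123, 2.345)})
        row = mid.points[10]
        assert row[1] == 0.123 and row[2] == 2.345

    def test_symmetric_section_deepest_at_axis(self):
        # symmetric V-profile: deepest point exactly at the symmetry ordinate
        ys = np.linspace(-1, 1, 21)
        zs = np.abs(ys) + 1.0
        sec = ot.PlanarSection(plane_x=0.0,
                               loops=[np.column_stack([ys, zs])],
                               loop_classes=[np.zeros(20, dtype=int)],
                               loop_closed=[False])
        square = Contour3D(np.array([[-1, -1, 0], [1, -1, 0],
                                     [1, 1, 0], [-1, 1, 0.0]]), closed=True)
        mid = ot.midline_from_sections([sec, sec], square)
        assert mid.points[0][1] == pytest.approx(0.0, abs=1e-12)

    def test_pit_filter_restores_valley(self):
        spec = st.SyntheticToothSpec()
        cap, truth = st.make_two_cusp_crown(spec)
        cap, _ = st.apply_wear_and_pits(cap, n_pits=5, seed=2)
        curv = vertex_curvature(cap.mesh)
        contour = ot.occlusal_contour_oes(cap, curv)
        secs = ot.section_series(cap, n=80, occlusal_contour=contour)
        naive = ot.midline_from_sections(secs, contour)
        filtered = ot.midline_from_sections(secs, contour, cap=cap,
                                            curvature=curv, pit_filter=True)
        bound = 2 * truth["resolution"]
        # this seed places a pit that fools the naive search
        assert np.abs(naive.points[:, 1]).max() > bound
        assert np.abs(filtered.points[:, 1]).max() <= bound
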