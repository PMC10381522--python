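import numpy as np
import pytest
from hypothesis import given, settings, strategies as hs

from enamelmap import SurfaceMesh, build_report, saet2d, saet3d
from enamelmap import occlusal_topography as ot
from enamelmap import sector_metrics as sm
from enamelmap import synthetic_tooth as st
from enamelmap.cap_segmentation import Contour3D
from enamelmap.errors import DomainError, ReportError

from conftest import parallel_plates, random_rotation

positive = hs.floats(min_value=1e-3, max_value=1e4,
                     allow_nan=False, allow_infinity=False)


class TestSaet3d:
    def test_equations_on_printed_occlusal_inputs(self):
        # SV/SAedj/SAoes as published for the Gigantopithecus occlusal total
        m = saet3d(170.60, 227.46, 249.96)
        assert m.SAA == pytest.approx(238.71, abs=1e-9)
        assert m.SAET3D == pytest.approx(0.71467, abs=5e-5)

    def test_equal_areas_reduce_to_classical_denominator(self):
        m = saet3d(10.0, 7.5, 7.5)
        assert m.SAA == 7.5
        assert m.SAET3D == m.aet_classical()

    def test_sphere_shell_closed_form(self):
        R, r = 1.1, 1.0
        m = saet3d(4 * np.pi * (R ** 3 - r ** 3) / 3,
                   4 * np.pi * r ** 2, 4 * np.pi * R ** 2)
        expected = (2 / 3) * (R ** 3 - r ** 3) / (R ** 2 + r ** 2)
        assert m.SAET3D == pytest.approx(expected, rel=1e-12)
        assert m.SAET3D == pytest.approx(0.09985, abs=1e-5)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(DomainError):
            saet3d(0.0, 1.0, 1.0)
        with pytest.raises(DomainError):
            saet3d(1.0, -2.0, 1.0)

    @settings(derandomize=True, max_examples=200)
    @given(sv=positive, sa_edj=positive, sa_oes=positive)
    def test_identities_exact(self, sv, sa_edj, sa_oes):
        m = saet3d(sv, sa_edj, sa_oes)
        assert m.SAA == (sa_edj + sa_oes) / 2.0
        assert m.SAET3D == sv / ((sa_edj + sa_oes) / 2.0)


class TestSaet2d:
    def test_rectangular_band(self):
        m = saet2d([[-5.0, 0.5], [5.0, 0.5]], [[-5.0, 0.0], [5.0, 0.0]])
        assert m.SA == pytest.approx(5.0, abs=1e-9)
        assert m.SCLoes == pytest.approx(10.0, abs=1e-12)
        assert m.SACL == pytest.approx(10.0, abs=1e-12)
        assert m.SAET2D == pytest.approx(0.5, abs=1e-9)

    def test_half_annulus(self):
        th = np.linspace(0, np.pi, 4001)
        R, r = 1.1, 1.0
        m = saet2d(np.column_stack([R * np.cos(th), R * np.sin(th)]),
                   np.column_stack([r * np.cos(th), r * np.sin(th)]))
        assert m.SA == pytest.approx(np.pi * (R ** 2 - r ** 2) / 2, rel=1e-4)
        assert m.SACL == pytest.approx(np.pi * (R + r) / 2, rel=1e-4)
        assert m.SAET2D == pytest.approx(0.1, rel=1e-3)

    def test_union_thickness_between_subsectors(self):
        # a step band: left half 0.4 thick, right half 0.8 thick
        oes = [[-4.0, 0.4], [0.0, 0.4], [0.0, 0.8], [4.0, 0.8]]
        left = saet2d([[-4.0, 0.4], [0.0, 0.4]], [[-4.0, 0.0], [0.0, 0.0]])
        right = saet2d([[0.0, 0.8], [4.0, 0.8]], [[0.0, 0.0], [4.0, 0.0]])
        union = saet2d(oes, [[-4.0, 0.0], [4.0, 0.0]])
        lo, hi = sorted([left.SAET2D, right.SAET2D])
        assert lo <= union.SAET2D <= hi

    @settings(derandomize=True, max_examples=200)
    @given(sa=positive, c1=positive, c2=positive)
    def test_identities_exact(self, sa, c1, c2):
        m = sm.SectorMeasurement2D("occlusal_total", sa, c1, c2)
        assert m.SACL == (c2 + c1) / 2.0
        assert m.SAET2D == sa / ((c2 + c1) / 2.0)


class TestPatchAreaAndVolume:
    def test_unit_square_two_triangles(self):
        mesh = SurfaceMesh(np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0],
                                     [0, 1, 0.0]]),
                           np.array([[0, 1, 2], [0, 2, 3]]))
        assert sm.patch_area(mesh, [0, 1]) == pytest.approx(1.0, abs=1e-12)

    def test_hemisphere_area(self, hemi_shell):
        cap, truth = hemi_shell
        # dome part of the outer class only (drop the stitched band)
        cent = cap.mesh.face_centroids()[cap.outer_faces]
        dome = cap.outer_faces[cent[:, 2] > 1e-6]
        assert sm.patch_area(cap.mesh, dome) == pytest.approx(
            truth["area_oes_dome"], rel=0.01)

    def test_area_rigid_invariance(self, crown):
        cap, _ = crown
        a0 = sm.patch_area(cap.mesh, cap.outer_faces)
        R = random_rotation(2)
        moved = SurfaceMesh(cap.mesh.vertices @ R.T + 3.0, cap.mesh.faces)
        a1 = sm.patch_area(moved, cap.outer_faces)
        assert a1 == pytest.approx(a0, rel=1e-9)

    def test_empty_patch_warns_zero(self, crown):
        cap, _ = crown
        with pytest.warns(UserWarning):
            assert sm.patch_area(cap.mesh, []) == 0.0

    def test_parallel_plates_volume(self):
        cap = parallel_plates(lx=2.0, ly=3.0, gap=0.5)
        sv = sm.sector_volume(cap, cap.outer_faces)
        assert sv == pytest.approx(3.0, rel=1e-9)

    def test_sphere_shell_volume(self, sphere_shell):
        cap, truth = sphere_shell
        sv = sm.sector_volume(cap, cap.outer_faces)
        assert sv == pytest.approx(truth["volume"], rel=0.005)


@pytest.fixture(scope="module")
def crown_patches(crown):
    cap, _ = crown
    contour = ot.occlusal_contour_oes(cap)
    contour_edj = ot.project_contour_to_edj(contour, cap)
    secs = ot.section_series(cap, n=80, occlusal_contour=contour)
    mid = ot.midline_from_sections(secs, contour)
    mid_edj = ot.project_contour_to_edj(mid, cap)
    return cap, sm.segment_sectors(cap, contour, contour_edj, mid, mid_edj)


class TestSegmentSectors:
    def test_partition(self, crown_patches):
        cap, patches = crown_patches
        for store in (patches.oes, patches.edj):
            occ = np.sort(store[sm.OCCLUSAL])
            parts = np.sort(np.concatenate([store[sm.BUCCAL],
                                            store[sm.LINGUAL]]))
            assert (occ == parts).all()

    def test_symmetric_crown_equal_slopes(self, crown_patches):
        cap, patches = crown_patches
        a_b = sm.patch_area(cap.mesh, patches.oes[sm.BUCCAL])
        a_l = sm.patch_area(cap.mesh, patches.oes[sm.LINGUAL])
        assert abs(a_b - a_l) / max(a_b, a_l) < 0.005

    def test_volume_additivity_and_symmetry(self, crown_patches):
        cap, patches = crown_patches
        meas = sm.measure_sectors(cap, patches)
        occ, b, l = (meas[s] for s in sm.SECTOR_IDS)
        assert abs(b.SV + l.SV - occ.SV) / occ.SV < 1e-3
        assert abs(b.SV - l.SV) / occ.SV < 0.005
        assert abs(b.SAoes + l.SAoes - occ.SAoes) / occ.SAoes < 1e-3

    def test_sphere_shell_quadrants(self):
        R, r = 2.0, 1.9
        cap, _ = st.make_hemisphere_shell(R, r, n_theta=256, n_phi=64)
        # equatorial 'contour' enclosing the whole cup and a meridian
        # 'midline': each slope sector is half the outer class (dome+band)
        th = np.linspace(0, 2 * np.pi, 200, endpoint=False)
        contour = Contour3D(np.column_stack([
            2.05 * np.cos(th), 2.05 * np.sin(th), np.zeros(200)]))
        xs = np.linspace(-2.1, 2.1, 50)
        midline = Contour3D(np.column_stack([xs, np.zeros(50), np.ones(50)]),
                            closed=False)
        patches = sm.segment_sectors(cap, contour, contour, midline, midline)
        half_outer = (2 * np.pi * R ** 2 + np.pi * (R ** 2 - r ** 2)) / 2
        areas = [sm.patch_area(cap.mesh, patches.oes[sid])
                 for sid in (sm.BUCCAL, sm.LINGUAL)]
        assert areas[0] == pytest.approx(areas[1], rel=1e-9)
        for a in areas:
            assert a == pytest.approx(half_outer, rel=0.01)

    def test_open_contour_rejected(self, crown):
        cap, _ = crown
        open_c = Contour3D(np.array([[0, 0, 3], [1, 0, 3], [1, 1, 3.0]]),
                           closed=False)
        midline = Contour3D(np.array([[-1, 0, 3], [1, 0, 3.0]]), closed=False)
        with pytest.raises(sm.SegmentationError):
            sm.segment_sectors(cap, open_c, open_c, midline, midline)


class TestReport:
    def test_printed_area_percentages(self):
        rep = build_report(saet3d(170.60, 227.46, 249.96),
                           saet3d(93.18, 122.61, 137.22, sm.BUCCAL),
                           saet3d(77.59, 104.85, 112.74, sm.LINGUAL))
        assert rep.percentages["SAoes"][sm.BUCCAL] == 54.90
        assert rep.percentages["SAoes"][sm.LINGUAL] == 45.10
        assert rep.percentages["SAoes"][sm.OCCLUSAL] == 100.0

    def test_printed_thickness_percentages(self):
        rep = build_report(saet3d(170.60, 227.46, 249.96),
                           saet3d(93.18, 122.61, 137.22, sm.BUCCAL),
                           saet3d(77.59, 104.85, 112.74, sm.LINGUAL),
                           thickness_values=(0.751, 0.764, 0.735))
        assert rep.percentages["SAET3D"][sm.BUCCAL] == 101.73
        assert rep.percentages["SAET3D"][sm.LINGUAL] == 97.87

    def test_equal_sectors_split_fifty_fifty(self):
        half = saet3d(5.0, 10.0, 10.0, sm.BUCCAL)
        total = saet3d(10.0, 20.0, 20.0)
        rep = build_report(total, half,
                           saet3d(5.0, 10.0, 10.0, sm.LINGUAL))
        assert rep.percentages["SV"][sm.BUCCAL] == 50.0
        assert rep.percentages["SV"][sm.LINGUAL] == 50.0
        assert rep.consistent

    def test_missing_sector_rejected(self):
        m = saet3d(1.0, 1.0, 1.0)
        with pytest.raises(ReportError):
            sm.ToothReport("x", {sm.OCCLUSAL: m})

    def test_rounding_half_up(self):
        assert sm._round2(54.895) == 54.9
        assert sm._round2(101.725) == 101.73
        assert sm._round2(45.104999) == 45.10


class TestThinShellLimit:
    @pytest.mark.parametrize("t_over_r", [0.02, 0.05, 0.1])
    def test_saet3d_recovers_thickness(self, t_over_r):
        R = 2.0
        r = R * (1 - t_over_r)
        cap, truth = st.make_sphere_shell(R, r, subdivisions=4)
        m = saet3d(sm.sector_volume(cap, cap.outer_faces),
                   sm.patch_area(cap.mesh, cap.inner_faces),
                   sm.patch_area(cap.mesh, cap.outer_faces))
        t = R - r
        assert abs(m.SAET3D - t) / t <= 0.02
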