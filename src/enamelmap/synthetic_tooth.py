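"""Synthetic enamel-cap fixtures with analytic ground truth.

Real micro-CT tooth surfaces are rarely redistributable, so every pipeline
stage is exercised on parametric stand-ins whose geometry is known in
closed form or by dense quadrature:

* concentric sphere shells (exact areas, volume and uniform thickness),
* an open hemispherical cup with a stitched cervical rim (exact rim
  circumference),
* a two-cusp molar-like crown: a height field with buccal and lingual
  cusps, mesial/distal marginal ridges and a mesio-distally running
  central valley at y = 0, closed at the cervix, with the EDJ built as an
  inward offset along the surface normals (uniform enamel thickness),
* a prismatic (extruded) enamel band for 2D/3D consistency checks.

Wear facets and surface pits/perforations emulate the taphonomic damage
seen on fossil molars. All randomness sits behind a single seed; the same
spec + seed reproduces vertex arrays bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import trimesh

from . import _geometry as geom
from .cap_segmentation import Contour3D, EnamelCap
from .errors import DomainError
from .mesh_io import SurfaceMesh

OUTER, INNER = 0, 1


@dataclass(frozen=True)
class SyntheticToothSpec:
    """Parameters of the two-cusp crown generator (all lengths in mm).

    Defaults approximate a great-ape lower-molar crown: an 11 x 9.5 mm
    elliptical footprint, ~3 mm of cuspal relief, buccal and lingual cusps
    separated by a central valley, mesial and distal marginal ridges, and
    a uniform 0.5 mm enamel layer.
    """

    footprint_semi_axes: tuple[float, float] = (5.5, 4.75)  # (mesio-distal, bucco-lingual)
    cusp_offset: float = 2.9        # cusp centres at y = +-cusp_offset
    cusp_height: float = 2.7
    cusp_width_y: float = 1.3       # bucco-lingual Gaussian width
    cusp_width_x: float = 3.2       # mesio-distal Gaussian width (ridge-like)
    wall_height: float = 2.0        # cervix-to-basin wall rise
    ridge_height: float = 1.2       # marginal-ridge amplitude
    ridge_radius: float = 0.55      # marginal-ridge position (fraction of footprint)
    ridge_width: float = 0.22      # radial width (fraction of footprint)
    ridge_band_width: float = 0.35  # bucco-lingual extent (fraction of footprint)
    groove_depth: float = 0.35      # central developmental groove along y = 0
    groove_width: float = 0.5
    thickness: float = 0.5          # uniform enamel thickness
    resolution: float = 0.25        # target edge length
    wear_depth: float = 0.0
    n_pits: int = 0                 # crater depressions on the OES
    pit_radius: float = 0.3
    pit_depth: float = 0.4
    n_perforations: int = 0         # punched holes in the OES
    perforation_radius: float = 0.2
    seed: int = 1234


# ---------------------------------------------------------------------------
# sphere shells


def make_sphere_shell(R: float, r: float, subdivisions: int = 4,
                      inner_subdivisions: int | None = None):
    """Concentric sphere shell: exact uniform thickness R - r.

    Returns ``(EnamelCap, truth)`` with closed-form areas, volume and
    thickness. The two spheres are separate closed components; face labels
    are attached as ground truth (outer sphere = OES, inner = EDJ).
    """
    if not R > r > 0:
        raise DomainError(f"need R > r > 0, got R={R}, r={r}")
    if inner_subdivisions is None:
        inner_subdivisions = subdivisions
    outer = trimesh.creation.icosphere(subdivisions=subdivisions, radius=R)
    inner = trimesh.creation.icosphere(subdivisions=inner_subdivisions, radius=r)
    v = np.vstack([outer.vertices, inner.vertices])
    f_outer = np.asarray(outer.faces)
    f_inner = np.asarray(inner.faces)[:, ::-1] + len(outer.vertices)  # inward
    faces = np.vstack([f_outer, f_inner])
    mesh = SurfaceMesh(v, faces, provenance=f"sphere shell R={R} r={r}")
    cap = EnamelCap(mesh, np.arange(len(f_outer)),
                    len(f_outer) + np.arange(len(f_inner)))
    truth = {
        "area_oes": 4 * np.pi * R ** 2,
        "area_edj": 4 * np.pi * r ** 2,
        "volume": 4 * np.pi * (R ** 3 - r ** 3) / 3,
        "thickness": R - r,
        "saet3d": (2.0 / 3.0) * (R ** 3 - r ** 3) / (R ** 2 + r ** 2),
    }
    return cap, truth


def make_hemisphere_shell(R: float, r: float, n_theta: int = 256,
                          n_phi: int = 48):
    """Open hemispherical cup: outer dome radius R, inner dome radius r,
    stitched at z = 0 by a flat annular cervical band.

    The analytic cervical edge (the OES/EDJ class border) is the inner rim
    circle, circumference ``2*pi*r``; the band is part of the outer class.
    """
    if not R > r > 0:
        raise DomainError(f"need R > r > 0, got R={R}, r={r}")

    def dome(radius, flip):
        vs, fs = [], []
        vs.append([0.0, 0.0, radius])  # pole
        for i in range(1, n_phi + 1):
            phi = 0.5 * np.pi * i / n_phi
            for j in range(n_theta):
                th = 2 * np.pi * j / n_theta
                vs.append([radius * np.sin(phi) * np.cos(th),
                           radius * np.sin(phi) * np.sin(th),
                           radius * np.cos(phi)])
        ring = lambda i: 1 + (i - 1) * n_theta
        for j in range(n_theta):
            fs.append([0, ring(1) + j, ring(1) + (j + 1) % n_theta])
        for i in range(1, n_phi):
            a, b = ring(i), ring(i + 1)
            for j in range(n_theta):
                j2 = (j + 1) % n_theta
                fs.append([a + j, b + j, b + j2])
                fs.append([a + j, b + j2, a + j2])
        vs, fs = np.array(vs), np.array(fs)
        if flip:
            fs = fs[:, ::-1]
        return vs, fs

    v_out, f_out = dome(R, flip=False)   # normals outward/up
    v_in, f_in = dome(r, flip=True)      # normals into the cup
    off = len(v_out)
    f_in = f_in + off
    # annular band at z=0 from outer rim to inner rim, facing -z
    rim_out = 1 + (n_phi - 1) * n_theta + np.arange(n_theta)
    rim_in = off + 1 + (n_phi - 1) * n_theta + np.arange(n_theta)
    band = []
    for j in range(n_theta):
        j2 = (j + 1) % n_theta
        band.append([rim_out[j], rim_in[j], rim_in[j2]])
        band.append([rim_out[j], rim_in[j2], rim_out[j2]])
    band = np.array(band)
    v = np.vstack([v_out, v_in])
    faces = np.vstack([f_out, f_in, band])
    faces = _fix_stitch_orientation(v, faces,
                                    np.arange(len(f_out) + len(f_in),
                                              len(faces)))
    mesh = SurfaceMesh(v, faces, provenance=f"hemisphere shell R={R} r={r}")
    outer_idx = np.concatenate([np.arange(len(f_out)),
                                len(f_out) + len(f_in) + np.arange(len(band))])
    inner_idx = len(f_out) + np.arange(len(f_in))
    cap = EnamelCap(mesh, outer_idx, inner_idx)
    truth = {
        "rim_circumference": 2 * np.pi * r,
        "area_oes_dome": 2 * np.pi * R ** 2,
        "area_edj_dome": 2 * np.pi * r ** 2,
        "volume": 2 * np.pi * (R ** 3 - r ** 3) / 3,
        "thickness": R - r,
    }
    return cap, truth


def _fix_stitch_orientation(vertices, faces, band_rows):
    """Flip stitch-band winding if any directed edge is duplicated, then
    make the total signed volume non-negative."""
    def directed_ok(fs):
        e = np.concatenate([fs[:, [0, 1]], fs[:, [1, 2]], fs[:, [2, 0]]])
        _, counts = np.unique(e, axis=0, return_counts=True)
        return (counts == 1).all()

    if not directed_ok(faces):
        faces = faces.copy()
        faces[band_rows] = faces[band_rows][:, ::-1]
    if geom.signed_volume(vertices, faces) < 0:
        faces = faces[:, ::-1]
    return faces


# ---------------------------------------------------------------------------
# two-cusp crown


def crown_height(x, y, spec: SyntheticToothSpec):
    """Analytic OES height field of the crown over its elliptic footprint."""
    a, b = spec.footprint_semi_axes
    xr, yr = np.asarray(x) / a, np.asarray(y) / b
    rho2 = xr ** 2 + yr ** 2
    rho = np.sqrt(rho2)
    wall = spec.wall_height * (1.0 - rho ** 3)
    taper = np.clip(1.0 - rho2, 0.0, None)
    bumps = 0.0
    for s in (+1.0, -1.0):
        bumps = bumps + spec.cusp_height * np.exp(
            -((np.asarray(y) - s * spec.cusp_offset) ** 2
              / (2 * spec.cusp_width_y ** 2)
              + np.asarray(x) ** 2 / (2 * spec.cusp_width_x ** 2)))
    # marginal ridges: a ring at rho ~ ridge_radius restricted to a smooth
    # bucco-lingual band |y/b| << 1, i.e. the mesial and distal crown ends
    ridge = spec.ridge_height * np.exp(
        -(rho - spec.ridge_radius) ** 2 / (2 * spec.ridge_width ** 2)
        - yr ** 2 / spec.ridge_band_width ** 2)
    # central developmental groove: keeps y = 0 the strict bucco-lingual
    # minimum of every occlusal section (the midline locus)
    groove = spec.groove_depth * np.exp(-(np.asarray(y) / spec.groove_width) ** 2)
    return wall + taper * bumps + ridge - groove


def _crown_normals(x, y, spec, h=1e-5):
    fx = (crown_height(x + h, y, spec) - crown_height(x - h, y, spec)) / (2 * h)
    fy = (crown_height(x, y + h, spec) - crown_height(x, y - h, spec)) / (2 * h)
    n = np.stack([-fx, -fy, np.ones_like(fx)], axis=-1)
    return n / np.linalg.norm(n, axis=-1, keepdims=True)


def _polar_grid(spec: SyntheticToothSpec):
    a, b = spec.footprint_semi_axes
    n_rho = max(8, int(np.ceil(0.5 * (a + b) / spec.resolution)))
    n_theta = max(16, int(np.ceil(np.pi * (a + b) / spec.resolution)))
    n_theta += n_theta % 2  # even, so the grid is mirror-symmetric about y=0
    return n_rho, n_theta


def _sheet_faces(n_rho, n_theta):
    """Triangulation of the polar grid (pole fan + quad strips)."""
    ring = lambda i: 1 + (i - 1) * n_theta
    fs = []
    for j in range(n_theta):
        fs.append([0, ring(1) + j, ring(1) + (j + 1) % n_theta])
    for i in range(1, n_rho):
        p, q = ring(i), ring(i + 1)
        for j in range(n_theta):
            j2 = (j + 1) % n_theta
            fs.append([p + j, q + j, q + j2])
            fs.append([p + j, q + j2, p + j2])
    return np.array(fs)


def make_two_cusp_crown(spec: SyntheticToothSpec | None = None,
                        with_truth_mesh: bool = False):
    """Two-cusp molar crown as an enamel cap of uniform thickness.

    The OES is the parametric height field of :func:`crown_height`; the
    EDJ is the inward offset by ``spec.thickness`` along the analytic OES
    normals; the sheets are stitched at the cervix by a band attributed to
    the outer class. Deterministic: the same spec gives bitwise-identical
    vertex arrays.

    Returns ``(EnamelCap, truth)`` where truth carries the ground-truth
    labels, the valley locus (y = 0), cusp apex positions, the EDJ cervical
    rim polyline, and dense-quadrature area/volume values.
    """
    spec = spec or SyntheticToothSpec()
    a, b = spec.footprint_semi_axes
    if spec.thickness <= 0:
        raise DomainError("enamel thickness must be positive")

    n_rho, n_theta = _polar_grid(spec)
    # curvature screen: an inward offset self-intersects where the surface
    # is convex with a radius of curvature below the enamel thickness.
    kappa = _max_convex_curvature(spec)
    if spec.thickness > 0.9 / max(kappa, 1e-9):
        raise DomainError(
            f"thickness {spec.thickness} mm exceeds the minimal convex "
            f"radius of curvature ({1.0 / kappa:.3f} mm); inward offset "
            f"would self-intersect")

    verts_param = [(0.0, 0.0)]
    for i in range(1, n_rho + 1):
        rho = i / n_rho
        for j in range(n_theta):
            th = 2 * np.pi * j / n_theta
            verts_param.append((a * rho * np.cos(th), b * rho * np.sin(th)))
    xy = np.array(verts_param)
    z = crown_height(xy[:, 0], xy[:, 1], spec)
    oes_v = np.column_stack([xy, z])
    normals = _crown_normals(xy[:, 0], xy[:, 1], spec)
    edj_v = oes_v - spec.thickness * normals

    f_oes = _sheet_faces(n_rho, n_theta)
    off = len(oes_v)
    f_edj = _sheet_faces(n_rho, n_theta)[:, ::-1] + off
    rim_oes = 1 + (n_rho - 1) * n_theta + np.arange(n_theta)
    rim_edj = off + 1 + (n_rho - 1) * n_theta + np.arange(n_theta)
    band = []
    for j in range(n_theta):
        j2 = (j + 1) % n_theta
        band.append([rim_oes[j], rim_edj[j], rim_edj[j2]])
        band.append([rim_oes[j], rim_edj[j2], rim_oes[j2]])
    band = np.array(band)
    v = np.vstack([oes_v, edj_v])
    faces = np.vstack([f_oes, f_edj, band])
    faces = _fix_stitch_orientation(
        v, faces, np.arange(len(f_oes) + len(f_edj), len(faces)))
    mesh = SurfaceMesh(v, faces, provenance="synthetic two-cusp crown")
    outer_idx = np.concatenate([np.arange(len(f_oes)),
                                len(f_oes) + len(f_edj) + np.arange(len(band))])
    inner_idx = len(f_oes) + np.arange(len(f_edj))
    cap = EnamelCap(mesh, outer_idx, inner_idx)

    truth = {
        "labels_outer": outer_idx.copy(),
        "labels_inner": inner_idx.copy(),
        "valley_y": 0.0,
        "apexes": _crown_apexes(spec),
        "edj_rim": v[rim_edj],
        "edj_rim_length": geom.polyline_length(v[rim_edj], closed=True),
        "thickness": spec.thickness,
        "resolution": spec.resolution,
        "spec": spec,
    }
    if with_truth_mesh:
        fine = replace(spec, resolution=spec.resolution / 2.0)
        fine_cap, _ = make_two_cusp_crown(fine, with_truth_mesh=False)
        truth["volume"] = geom.signed_volume(fine_cap.mesh.vertices,
                                             fine_cap.mesh.faces)
        truth["area_oes"] = fine_cap.outer_submesh().area
        truth["area_edj"] = fine_cap.inner_submesh().area
    return cap, truth


def _max_convex_curvature(spec: SyntheticToothSpec, n: int = 161) -> float:
    """Largest convex principal curvature of the OES height field."""
    a, b = spec.footprint_semi_axes
    g = np.linspace(-0.97, 0.97, n)
    X, Y = np.meshgrid(g * a, g * b)
    m = (X / a) ** 2 + (Y / b) ** 2 <= 0.95 ** 2
    h = 1e-4
    f = lambda x, y: crown_height(x, y, spec)
    fx = (f(X + h, Y) - f(X - h, Y)) / (2 * h)
    fy = (f(X, Y + h) - f(X, Y - h)) / (2 * h)
    fxx = (f(X + h, Y) - 2 * f(X, Y) + f(X - h, Y)) / h ** 2
    fyy = (f(X, Y + h) - 2 * f(X, Y) + f(X, Y - h)) / h ** 2
    fxy = (f(X + h, Y + h) - f(X + h, Y - h)
           - f(X - h, Y + h) + f(X - h, Y - h)) / (4 * h ** 2)
    w = np.sqrt(1 + fx ** 2 + fy ** 2)
    # shape operator II * I^-1 for a graph, upward normal
    E, F, G = 1 + fx ** 2, fx * fy, 1 + fy ** 2
    L, M, N = fxx / w, fxy / w, fyy / w
    det_i = E * G - F * F
    a11 = (L * G - M * F) / det_i
    a12 = (M * G - N * F) / det_i
    a21 = (M * E - L * F) / det_i
    a22 = (N * E - M * F) / det_i
    tr, det = a11 + a22, a11 * a22 - a12 * a21
    disc = np.sqrt(np.maximum(tr ** 2 / 4 - det, 0.0))
    lam_min = tr / 2 - disc  # most convex direction (negative at a peak)
    return float(np.maximum(-lam_min, 0.0)[m].max())


def _crown_apexes(spec: SyntheticToothSpec):
    """Cusp apex (x, y, z) positions by dense search on the height field."""
    a, b = spec.footprint_semi_axes
    apexes = []
    for s in (+1.0, -1.0):
        gx = np.linspace(-0.4 * a, 0.4 * a, 161)
        gy = np.linspace(s * spec.cusp_offset - 1.5,
                         s * spec.cusp_offset + 1.5, 161)
        X, Y = np.meshgrid(gx, gy)
        Z = crown_height(X, Y, spec)
        k = np.argmax(Z)
        apexes.append([X.ravel()[k], Y.ravel()[k], Z.ravel()[k]])
    return np.array(apexes)


# ---------------------------------------------------------------------------
# prismatic (extruded) band for 2D/3D consistency


def make_prismatic_band(length: float = 8.0, width: float = 8.0,
                        arch_height: float = 2.0, thickness: float = 0.5,
                        resolution: float = 0.2):
    """Extruded enamel band: a parabolic arch profile of uniform thickness.

    The cross-section is identical at every x, so the mean sectional
    SAET2D must match the volumetric SAET3D. Open at the ends and sides
    (no cervical stitch); OES and EDJ remain separate labeled sheets.
    """
    ny = max(8, int(np.ceil(width / resolution)))
    nx = max(4, int(np.ceil(length / resolution)))
    ys = np.linspace(-width / 2, width / 2, ny + 1)
    xs = np.linspace(-length / 2, length / 2, nx + 1)
    g = arch_height * (1.0 - (2 * ys / width) ** 2)
    dg = -8.0 * arch_height * ys / width ** 2
    nrm = np.sqrt(1.0 + dg ** 2)
    y_edj = ys + thickness * dg / nrm
    z_edj = g - thickness / nrm

    def sheet(yy, zz, flip):
        vs = np.array([[x, y, z] for x in xs for y, z in zip(yy, zz)])
        fs = []
        for i in range(nx):
            for j in range(ny):
                p = i * (ny + 1) + j
                q = (i + 1) * (ny + 1) + j
                fs.append([p, q, q + 1])
                fs.append([p, q + 1, p + 1])
        fs = np.array(fs)
        if flip:
            fs = fs[:, ::-1]
        return vs, fs

    v_oes, f_oes = sheet(ys, g, flip=False)
    v_edj, f_edj = sheet(y_edj, z_edj, flip=True)
    v = np.vstack([v_oes, v_edj])
    faces = np.vstack([f_oes, f_edj + len(v_oes)])
    # orient OES upward
    if geom.face_normals(v, faces[: len(f_oes)])[:, 2].mean() < 0:
        faces[: len(f_oes)] = faces[: len(f_oes)][:, ::-1]
    if geom.face_normals(v, faces[len(f_oes):])[:, 2].mean() > 0:
        faces[len(f_oes):] = faces[len(f_oes):][:, ::-1]
    mesh = SurfaceMesh(v, faces, provenance="synthetic prismatic band")
    cap = EnamelCap(mesh, np.arange(len(f_oes)),
                    len(f_oes) + np.arange(len(f_edj)))
    # dense 2D truth for the cross-section
    yd = np.linspace(-width / 2, width / 2, 4001)
    gd = arch_height * (1.0 - (2 * yd / width) ** 2)
    dgd = -8.0 * arch_height * yd / width ** 2
    nd = np.sqrt(1.0 + dgd ** 2)
    oes_len = np.trapezoid(nd, yd)
    edj_pts = np.column_stack([yd + thickness * dgd / nd, gd - thickness / nd])
    edj_len = geom.polyline_length(edj_pts)
    poly = np.vstack([np.column_stack([yd, gd]), edj_pts[::-1]])
    sa = abs(geom.polygon_signed_area(poly))
    truth = {
        "thickness": thickness,
        "sa_2d": sa,
        "scl_oes": oes_len,
        "scl_edj": edj_len,
        "saet2d": sa / (0.5 * (oes_len + edj_len)),
    }
    return cap, truth


# ---------------------------------------------------------------------------
# wear and pits


def apply_wear_and_pits(cap: EnamelCap, wear_depth: float = 0.0,
                        n_pits: int = 0, pit_radius: float = 0.3,
                        pit_depth: float = 0.4, n_perforations: int = 0,
                        perforation_radius: float = 0.2,
                        seed: int = 1234):
    """Add occlusal wear, crater pits and perforations to a cap.

    * wear: both surfaces are clipped at ``z_max - wear_depth``; EDJ
      vertices that reached the cut plane are reported as exposed dentine;
    * pits: crater-shaped depressions pressed into the OES (these mislead
      a naive deepest-point search and exercise the midline pit filter);
    * perforations: OES faces punched out around random centres (each
      adds one boundary loop, exercising hole filling).

    Returns ``(cap, info)`` with ``info['exposed_edj_vertices']`` and
    ``info['pit_centers']``.
    """
    rng = np.random.default_rng(seed)
    mesh = cap.mesh
    v = mesh.vertices.copy()
    faces = mesh.faces.copy()
    info: dict = {"pit_centers": [], "perforation_centers": [],
                  "exposed_edj_vertices": np.array([], dtype=int)}

    outer_vertex = np.zeros(len(v), dtype=bool)
    outer_vertex[np.unique(faces[cap.outer_faces])] = True
    inner_vertex = np.zeros(len(v), dtype=bool)
    inner_vertex[np.unique(faces[cap.inner_faces])] = True

    if wear_depth > 0:
        z_cut = v[:, 2].max() - wear_depth
        if z_cut <= v[:, 2].min():
            raise DomainError("wear depth removes the whole crown")
        exposed = np.flatnonzero(inner_vertex & (v[:, 2] > z_cut))
        info["exposed_edj_vertices"] = exposed
        v[:, 2] = np.minimum(v[:, 2], z_cut)

    # candidate centres: upper-crown OES vertices
    cand = np.flatnonzero(outer_vertex
                          & (v[:, 2] > np.percentile(v[outer_vertex, 2], 60)))

    for _ in range(n_pits):
        c = v[rng.choice(cand)]
        d = np.linalg.norm(v[:, :2] - c[:2], axis=1)
        m = outer_vertex & (d < pit_radius) & (np.abs(v[:, 2] - c[2]) < 2 * pit_radius)
        v[m, 2] -= pit_depth * np.cos(0.5 * np.pi * d[m] / pit_radius) ** 2
        info["pit_centers"].append(c.copy())

    keep = np.ones(len(faces), dtype=bool)
    for _ in range(n_perforations):
        c = v[rng.choice(cand)]
        fc = geom.face_centroids(v, faces)
        d = np.linalg.norm(fc - c, axis=1)
        m = keep & (d < perforation_radius)
        m &= np.isin(np.arange(len(faces)), cap.outer_faces)
        if not m.any():  # enlarge until at least one face goes
            m = keep & np.isin(np.arange(len(faces)), cap.outer_faces)
            m &= d < d[m].min() * 1.001 if m.any() else m
        keep &= ~m
        info["perforation_centers"].append(c.copy())

    new_index = np.cumsum(keep) - 1
    new_faces = faces[keep]
    out_mask = np.zeros(len(faces), dtype=bool)
    out_mask[cap.outer_faces] = True
    new_outer = new_index[np.flatnonzero(out_mask & keep)]
    new_inner = new_index[np.flatnonzero(~out_mask & keep)]
    new_mesh = SurfaceMesh(v, new_faces, mesh.provenance + " +wear/pits")
    new_cap = EnamelCap(new_mesh, new_outer, new_inner, None, cap.mass_center)
    return new_cap, info
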