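"""Occlusal-surface topography: curvature, contours, sections, midline.

The occlusal surface of a posterior tooth is bounded by the cusp and
marginal ridges. Its contour is found on the oriented OES as a closed
crest cycle: a radial sweep about the crown axis proposes the highest OES
vertex per azimuth, and consecutive proposals are joined by minimal-cost
paths whose edge cost favours convex (ridge-like) curvature. The contour
is then cast along -z onto the EDJ surface. Bucco-lingual planar sections
(80 by default) and the per-section deepest occlusal points give the
mesio-distally running midline separating the buccal from the lingual
part of the crown.

All operations expect the cap already in tooth-frame coordinates
(+z occlusal, x mesio-distal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree
from shapely.geometry import LineString, Point, Polygon

from . import _geometry as geom
from .cap_segmentation import Contour3D, EnamelCap, INNER, OUTER
from .errors import ContourFailureError, ProjectionFailureError
from .mesh_io import SurfaceMesh

RIDGE_COST_EPSILON = 1e-3  # 1/mm; bounds ridge-path costs on flat saddles


@dataclass
class CurvatureField:
    """Per-vertex discrete mean curvature (1/mm); convex positive."""

    values: np.ndarray
    boundary: np.ndarray  # True where the one-ring is open (value unreliable)

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        self.boundary = np.asarray(self.boundary, bool)


@dataclass
class PlanarSection:
    """A bucco-lingual mesh section: closed loops in the (y, z) plane.

    ``loop_classes[i][k]`` labels the segment from point k to k+1 of loop i
    with the class (OUTER/INNER) of the face it came from.
    """

    plane_x: float
    loops: list = field(default_factory=list)          # (K,2) arrays (y, z)
    loop_classes: list = field(default_factory=list)   # (K,) int arrays
    loop_closed: list = field(default_factory=list)    # bool per loop

    @property
    def is_empty(self) -> bool:
        return len(self.loops) == 0

    def class_chains(self, cls: int):
        """Contiguous polyline runs of a given segment class, as (K,2) arrays."""
        chains = []
        for pts, classes, closed in zip(self.loops, self.loop_classes,
                                        self.loop_closed):
            n = len(classes)
            if n == 0:
                continue
            mask = classes == cls
            if mask.all() and closed:
                chains.append(np.vstack([pts, pts[:1]]))
                continue
            if not mask.any():
                continue
            # walk runs of consecutive True segments (cyclic when closed)
            idx = np.flatnonzero(mask)
            runs = []
            run = [idx[0]]
            for k in idx[1:]:
                if k == run[-1] + 1:
                    run.append(k)
                else:
                    runs.append(run)
                    run = [k]
            runs.append(run)
            if closed and len(runs) > 1 and runs[0][0] == 0 \
                    and runs[-1][-1] == n - 1:
                runs[0] = runs.pop() + runs[0]
            npts = len(pts)
            for run in runs:
                vids = [run[0]] + [(k + 1) % npts for k in run]
                chains.append(pts[np.array(vids)])
        return chains


def vertex_curvature(mesh: SurfaceMesh) -> CurvatureField:
    """Discrete mean curvature per vertex (cotangent Laplacian).

    The mean-curvature vector is ``K_i = (1/2A_i) sum_j (cot a + cot b)
    (x_i - x_j)``; its projection on the outward vertex normal gives
    ``2H``, positive where the surface is convex (cusp-like). Boundary and
    isolated vertices are flagged and set to 0.
    """
    v, f = mesh.vertices, mesh.faces
    n = len(v)
    # cotangents at each face corner
    cot = np.empty((len(f), 3))
    for k in range(3):
        a = v[f[:, (k + 1) % 3]] - v[f[:, k]]
        b = v[f[:, (k + 2) % 3]] - v[f[:, k]]
        cross = np.linalg.norm(np.cross(a, b), axis=1)
        cross[cross == 0] = 1e-30
        cot[:, k] = np.einsum("ij,ij->i", a, b) / cross
    # edge (j,k) opposite corner i gets weight cot_i
    rows, cols, vals = [], [], []
    for k in range(3):
        i, j = f[:, (k + 1) % 3], f[:, (k + 2) % 3]
        rows.extend([i, j])
        cols.extend([j, i])
        vals.extend([cot[:, k], cot[:, k]])
    W = coo_matrix((np.concatenate(vals),
                    (np.concatenate(rows), np.concatenate(cols))),
                   shape=(n, n)).tocsr()
    deg = np.asarray(W.sum(axis=1)).ravel()
    lap = deg[:, None] * v - W @ v  # sum w_ij (x_i - x_j)

    # Meyer mixed Voronoi areas: accurate at irregular-valence vertices
    areas = geom.face_areas(v, f)
    a_mixed = np.zeros(n)
    obtuse_at = cot < 0  # corner angle > 90 deg
    any_obtuse = obtuse_at.any(axis=1)
    for k in range(3):
        j1, j2 = (k + 1) % 3, (k + 2) % 3
        e1 = np.einsum("ij,ij->i", v[f[:, j1]] - v[f[:, k]],
                       v[f[:, j1]] - v[f[:, k]])
        e2 = np.einsum("ij,ij->i", v[f[:, j2]] - v[f[:, k]],
                       v[f[:, j2]] - v[f[:, k]])
        voronoi = (e2 * cot[:, j1] + e1 * cot[:, j2]) / 8.0
        contrib = np.where(any_obtuse,
                           np.where(obtuse_at[:, k], areas / 2.0, areas / 4.0),
                           voronoi)
        np.add.at(a_mixed, f[:, k], contrib)

    normals = geom.vertex_normals(v, f)
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.einsum("ij,ij->i", lap, normals) / (4.0 * a_mixed)
    h[~np.isfinite(h)] = 0.0

    boundary = np.zeros(n, dtype=bool)
    be = geom.boundary_edges(f)
    if len(be):
        boundary[np.unique(be)] = True
    used = np.zeros(n, dtype=bool)
    used[np.unique(f)] = True
    boundary |= ~used
    h[boundary] = 0.0
    return CurvatureField(h, boundary)


# ---------------------------------------------------------------------------
# occlusal contour on the OES


def _oes_vertex_graph(cap: EnamelCap):
    """Vertex ids and unique edges of the OES submesh."""
    faces = cap.mesh.faces[cap.outer_faces]
    edges, _, _ = geom.unique_edges(faces)
    vids = np.unique(faces)
    return vids, edges


def _crest_picks(points: np.ndarray, center_xy: np.ndarray, n_bins: int):
    """Highest point per azimuth bin about the crown axis."""
    d = points[:, :2] - center_xy
    theta = np.arctan2(d[:, 1], d[:, 0])
    bins = ((theta + np.pi) / (2 * np.pi) * n_bins).astype(int) % n_bins
    picks = np.full(n_bins, -1)
    for b in range(n_bins):
        m = np.flatnonzero(bins == b)
        if len(m):
            picks[b] = m[np.argmax(points[m, 2])]
    return picks[picks >= 0]


def find_cusp_apexes(cap: EnamelCap, n: int = 2,
                     min_separation: float | None = None) -> np.ndarray:
    """Vertex ids of the n highest OES points with mutual xy separation."""
    vids = np.unique(cap.mesh.faces[cap.outer_faces])
    pts = cap.mesh.vertices[vids]
    if min_separation is None:
        span = pts[:, :2].max(0) - pts[:, :2].min(0)
        min_separation = 0.25 * float(span.min())
    order = np.argsort(pts[:, 2])[::-1]
    chosen: list[int] = []
    for k in order:
        if all(np.linalg.norm(pts[k, :2] - pts[c, :2]) >= min_separation
               for c in chosen):
            chosen.append(k)
        if len(chosen) == n:
            break
    return vids[np.array(chosen)]


def occlusal_contour_oes(cap: EnamelCap, curvature: CurvatureField | None = None,
                         overrides: np.ndarray | None = None,
                         n_bins: int = 96) -> Contour3D:
    """Closed crest loop on the OES bounding the occlusal surface.

    Without overrides, a radial sweep proposes the highest OES vertex per
    azimuth bin (the cusp/marginal-ridge crest) and consecutive proposals
    are connected by minimal-cost paths with edge cost
    ``length / (eps + max(0, curvature))``. With overrides, the supplied
    points are snapped to the nearest OES vertices and joined along
    geodesics instead.
    """
    mesh = cap.mesh
    vids, edges = _oes_vertex_graph(cap)
    pts_all = mesh.vertices

    if curvature is None:
        curvature = vertex_curvature(mesh)

    if overrides is not None:
        overrides = np.asarray(overrides, float).reshape(-1, 3)
        tree = cKDTree(pts_all[vids])
        _, snap = tree.query(overrides)
        waypoints = vids[snap]
        elen = np.linalg.norm(pts_all[edges[:, 0]] - pts_all[edges[:, 1]], axis=1)
        cost = elen
    else:
        apexes = find_cusp_apexes(cap, n=2)
        center_xy = pts_all[apexes][:, :2].mean(axis=0)
        oes_pts = pts_all[vids]
        picks_local = _crest_picks(oes_pts, center_xy, n_bins)
        waypoints = vids[picks_local]
        # keep the search inside the crest band so the ridge path cannot
        # detour down the outer wall toward the (convex) cervical margin
        z_floor = pts_all[waypoints][:, 2].min() - 0.1 * (
            pts_all[waypoints][:, 2].max() - pts_all[vids][:, 2].min() + 1e-9)
        in_band = (pts_all[edges[:, 0], 2] >= z_floor) \
            & (pts_all[edges[:, 1], 2] >= z_floor)
        edges = edges[in_band]
        elen = np.linalg.norm(pts_all[edges[:, 0]] - pts_all[edges[:, 1]], axis=1)
        kappa = 0.5 * (curvature.values[edges[:, 0]]
                       + curvature.values[edges[:, 1]])
        kappa = np.maximum(0.0, kappa)
        if (kappa > 0).any():
            # cap the convexity reward: isolated spikes (pit rims, mesh
            # noise) must not out-attract the genuine crest ridge
            kappa = np.minimum(kappa, np.percentile(kappa[kappa > 0], 90))
        cost = elen / (RIDGE_COST_EPSILON + kappa)

    nv = len(pts_all)
    g = coo_matrix((np.concatenate([cost, cost]),
                    (np.concatenate([edges[:, 0], edges[:, 1]]),
                     np.concatenate([edges[:, 1], edges[:, 0]]))),
                   shape=(nv, nv)).tocsr()

    loop: list[int] = []
    wp = list(dict.fromkeys(int(w) for w in waypoints))  # dedupe, keep order
    for i, src in enumerate(wp):
        dst = wp[(i + 1) % len(wp)]
        if src == dst:
            continue
        dist, pred = dijkstra(g, indices=src, return_predecessors=True)
        if not np.isfinite(dist[dst]):
            raise ContourFailureError(
                "crest waypoints are not connected on the OES; supply "
                "contour overrides")
        path = [dst]
        while path[-1] != src:
            path.append(int(pred[path[-1]]))
        loop.extend(path[::-1][:-1])
    if len(loop) < 3:
        raise ContourFailureError("occlusal contour collapsed; supply overrides")
    # collapse retraced spurs (a-b-...-b-a) until the cycle is stable
    cleaned = loop
    changed = True
    while changed and len(cleaned) >= 3:
        changed = False
        out: list[int] = []
        n = len(cleaned)
        i = 0
        while i < n:
            vid = cleaned[i]
            if len(out) >= 2 and out[-2] == vid:
                out.pop()
                changed = True
            else:
                out.append(vid)
            i += 1
        # wrap-around spur
        while len(out) >= 3 and out[0] == out[-2]:
            out = out[:-2]
            changed = True
        cleaned = out
    if len(cleaned) < 3:
        raise ContourFailureError("occlusal contour collapsed; supply overrides")
    contour = Contour3D(pts_all[np.array(cleaned)], closed=True)
    if geom.polygon_signed_area(contour.points[:, :2]) < 0:
        contour = Contour3D(contour.points[::-1], closed=True)

    if overrides is None:
        apex_pts = pts_all[find_cusp_apexes(cap, n=2)]
        poly = Polygon(contour.points[:, :2])
        if not poly.is_valid:
            poly = poly.buffer(0)
        edge_len = float(np.median(np.linalg.norm(
            pts_all[edges[:, 0]] - pts_all[edges[:, 1]], axis=1)))
        ok = sum(poly.buffer(2 * edge_len).contains(Point(p[:2]))
                 for p in apex_pts)
        if ok < 2:
            raise ContourFailureError(
                "occlusal contour does not enclose two cusp apices; "
                "supply overrides")
    return contour


def project_contour_to_edj(contour: Contour3D, cap: EnamelCap) -> Contour3D:
    """Cast each contour point along -z onto the EDJ surface.

    Points with no intersection are interpolated from projecting
    neighbours; if more than 20% fail, the projection is rejected.
    """
    edj = cap.inner_submesh()
    pts = contour.points
    z_hit, hit = geom.raycast_down(pts, edj.vertices, edj.faces)
    n_miss = int((~hit).sum())
    if n_miss > 0.2 * len(pts):
        raise ProjectionFailureError(
            f"{n_miss}/{len(pts)} contour points failed to project onto "
            f"the EDJ")
    out = pts.copy()
    out[hit, 2] = z_hit[hit]
    if n_miss:
        idx = np.arange(len(pts))
        good = idx[hit]
        dz_good = z_hit[hit] - pts[hit, 2]
        if contour.closed:  # circular interpolation of the z shift
            ext_idx = np.concatenate([good - len(pts), good, good + len(pts)])
            ext_dz = np.tile(dz_good, 3)
            dz = np.interp(idx[~hit], ext_idx, ext_dz)
        else:
            dz = np.interp(idx[~hit], good, dz_good)
        out[~hit, 2] = pts[~hit, 2] + dz
    return Contour3D(out, closed=contour.closed)


# ---------------------------------------------------------------------------
# section series and midline


def section_series(cap: EnamelCap, n: int = 80,
                   occlusal_contour: Contour3D | None = None,
                   span: str = "occlusal") -> list[PlanarSection]:
    """n bucco-lingual sections uniformly spaced along the mesio-distal axis.

    ``span='occlusal'`` limits the series to the occlusal contour's
    x-extent (requires the contour); ``span='crown'`` uses the whole mesh.
    Planes that miss the mesh yield empty sections.
    """
    if n < 3:
        raise ValueError("need n >= 3 sections")
    if span == "occlusal" and occlusal_contour is not None:
        x0 = occlusal_contour.points[:, 0].min()
        x1 = occlusal_contour.points[:, 0].max()
    else:
        x0 = cap.mesh.vertices[:, 0].min()
        x1 = cap.mesh.vertices[:, 0].max()
    cls = cap.face_class
    xs = x0 + np.arange(1, n + 1) * (x1 - x0) / (n + 1)
    sections = []
    for x in xs:
        sec = PlanarSection(plane_x=float(x))
        for pts, seg_cls, closed in geom.plane_section_loops(
                cap.mesh.vertices, cap.mesh.faces, cls, float(x)):
            sec.loops.append(pts)
            sec.loop_classes.append(seg_cls)
            sec.loop_closed.append(closed)
        sections.append(sec)
    return sections


def _contour_y_window(contour: Contour3D, x: float):
    """Bucco-lingual range of a closed contour at mesio-distal position x."""
    poly = Polygon(contour.points[:, :2])
    if not poly.is_valid:
        poly = poly.buffer(0)
    ymin, ymax = contour.points[:, 1].min() - 1.0, contour.points[:, 1].max() + 1.0
    cut = poly.intersection(LineString([(x, ymin), (x, ymax)]))
    if cut.is_empty:
        return None
    return cut.bounds[1], cut.bounds[3]


def midline_from_sections(sections: list[PlanarSection],
                          occlusal_oes: Contour3D,
                          overrides: dict[int, tuple[float, float]] | None = None,
                          cap: EnamelCap | None = None,
                          curvature: CurvatureField | None = None,
                          pit_filter: bool = False,
                          pit_percentile: float = 1.0) -> Contour3D:
    """Deepest OES point per section, chained into the mesio-distal midline.

    Per section, the candidate set is the OES chain points whose y lies in
    the occlusal contour's bucco-lingual window at that x; the deepest
    (minimal z) candidate wins. Ties within 1e-6 mm go to the candidate
    closest to the previous section's midline y (first section: closest to
    y = 0). With ``pit_filter``, candidates whose mapped vertex curvature
    falls below the given percentile of the OES curvature distribution
    (strongly concave pit walls/floors) are suppressed first. ``overrides``
    maps section index -> (y, z), replacing the automatic point verbatim.
    Sections with no usable candidates are skipped.
    """
    overrides = overrides or {}
    kappa_tree = kappa_vals = kappa_thresh = None
    if pit_filter:
        if cap is None:
            raise ValueError("pit_filter requires the cap")
        if curvature is None:
            curvature = vertex_curvature(cap.mesh)
        vids = np.unique(cap.mesh.faces[cap.outer_faces])
        interior = vids[~curvature.boundary[vids]]
        kappa_tree = cKDTree(cap.mesh.vertices[interior])
        kappa_vals = curvature.values[interior]
        kappa_thresh = float(np.percentile(kappa_vals, pit_percentile))

    points = []
    prev_y = 0.0
    for i, sec in enumerate(sections):
        if i in overrides:
            y, z = overrides[i]
            points.append([sec.plane_x, y, z])
            prev_y = y
            continue
        window = _contour_y_window(occlusal_oes, sec.plane_x)
        if window is None or sec.is_empty:
            continue
        cands = []
        for chain in sec.class_chains(OUTER):
            m = (chain[:, 0] >= window[0]) & (chain[:, 0] <= window[1])
            if m.any():
                cands.append(chain[m])
        if not cands:
            continue
        cand = np.unique(np.vstack(cands), axis=0)
        if pit_filter:
            p3 = np.column_stack([np.full(len(cand), sec.plane_x), cand])
            _, nearest = kappa_tree.query(p3)
            keep = kappa_vals[nearest] >= kappa_thresh
            if keep.any():
                cand = cand[keep]
        zmin = cand[:, 1].min()
        tie = cand[np.abs(cand[:, 1] - zmin) < 1e-6]
        best = tie[np.argmin(np.abs(tie[:, 0] - prev_y))]
        points.append([sec.plane_x, best[0], best[1]])
        prev_y = best[0]
    if len(points) < 2:
        raise ContourFailureError("midline could not be built from sections")
    return Contour3D(np.array(points), closed=False)
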