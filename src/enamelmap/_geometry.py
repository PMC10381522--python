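"""Low-level triangle-mesh geometry kernels shared across the pipeline.

All routines are pure functions on ``(vertices, faces)`` arrays in mm.
Spatial queries (nearest point on a surface, vertical ray casting) use a
KD-tree candidate search followed by exact point/triangle tests, which is
adequate for the smooth, moderately sized meshes this package targets.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree


# ---------------------------------------------------------------------------
# basic per-face quantities


def face_cross(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    v0, v1, v2 = (vertices[faces[:, i]] for i in range(3))
    return np.cross(v1 - v0, v2 - v0)


def face_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    return 0.5 * np.linalg.norm(face_cross(vertices, faces), axis=1)


def face_normals(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    c = face_cross(vertices, faces)
    n = np.linalg.norm(c, axis=1)
    n[n == 0] = 1.0
    return c / n[:, None]


def face_centroids(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    return vertices[faces].mean(axis=1)


def signed_volume(vertices: np.ndarray, faces: np.ndarray) -> float:
    """Signed enclosed volume by the divergence theorem (positive = outward)."""
    v0, v1, v2 = (vertices[faces[:, i]] for i in range(3))
    return float(np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum() / 6.0)


def total_area(vertices: np.ndarray, faces: np.ndarray) -> float:
    return float(face_areas(vertices, faces).sum())


def area_centroid(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Area-weighted centroid of the triangulated surface."""
    a = face_areas(vertices, faces)
    if a.sum() <= 0:
        raise ValueError("zero total surface area")
    return (face_centroids(vertices, faces) * a[:, None]).sum(axis=0) / a.sum()


def vertex_normals(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Area-weighted vertex normals."""
    fn = face_cross(vertices, faces)  # area-weighted by construction
    vn = np.zeros_like(vertices)
    for i in range(3):
        np.add.at(vn, faces[:, i], fn)
    n = np.linalg.norm(vn, axis=1)
    n[n == 0] = 1.0
    return vn / n[:, None]


# ---------------------------------------------------------------------------
# edges, boundaries, loops


def unique_edges(faces: np.ndarray):
    """Return (edges (E,2) sorted, counts, edge_faces list-of-arrays)."""
    e = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    e = np.sort(e, axis=1)
    edges, inverse, counts = np.unique(e, axis=0, return_inverse=True, return_counts=True)
    return edges, inverse, counts


def boundary_edges(faces: np.ndarray) -> np.ndarray:
    edges, _, counts = unique_edges(faces)
    return edges[counts == 1]


def chain_edges(edge_list: np.ndarray):
    """Chain an (E,2) vertex-index edge soup into loops and open chains.

    Returns ``(loops, chains)`` where each entry is an ordered vertex-index
    array; loops do not repeat the first vertex at the end.
    """
    adj: dict[int, list[int]] = {}
    for a, b in edge_list:
        adj.setdefault(int(a), []).append(int(b))
        adj.setdefault(int(b), []).append(int(a))

    unused = {tuple(sorted((int(a), int(b)))) for a, b in edge_list}
    loops, chains = [], []

    def walk(start: int, nxt: int):
        path = [start, nxt]
        unused.discard(tuple(sorted((start, nxt))))
        while True:
            cur, prev = path[-1], path[-2]
            cand = [v for v in adj[cur]
                    if tuple(sorted((cur, v))) in unused]
            if not cand:
                return path
            nxt2 = cand[0] if cand[0] != prev or len(cand) == 1 else cand[-1]
            unused.discard(tuple(sorted((cur, nxt2))))
            path.append(nxt2)
            if nxt2 == start:
                return path

    # open chains first (endpoints have odd degree)
    endpoints = sorted(v for v, nb in adj.items() if len(nb) % 2 == 1)
    for v in endpoints:
        while any(tuple(sorted((v, w))) in unused for w in adj[v]):
            w = next(w for w in adj[v] if tuple(sorted((v, w))) in unused)
            chains.append(np.array(walk(v, w)))
    while unused:
        a, b = sorted(unused)[0]
        path = walk(a, b)
        if path[0] == path[-1]:
            loops.append(np.array(path[:-1]))
        else:  # degenerate; keep as chain
            chains.append(np.array(path))
    return loops, chains


def boundary_loops(faces: np.ndarray):
    """Vertex-index loops of the mesh boundary (edges used by one face)."""
    be = boundary_edges(faces)
    if len(be) == 0:
        return []
    loops, chains = chain_edges(be)
    return loops + chains


def polyline_length(points: np.ndarray, closed: bool = False) -> float:
    if len(points) < 2:
        return 0.0
    d = np.linalg.norm(np.diff(points, axis=0), axis=1).sum()
    if closed:
        d += np.linalg.norm(points[0] - points[-1])
    return float(d)


def resample_polyline(points: np.ndarray, n: int, closed: bool = False) -> np.ndarray:
    """Resample a polyline at n points uniformly spaced in arc length."""
    pts = np.vstack([points, points[:1]]) if closed else np.asarray(points, float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] == 0:
        return np.repeat(pts[:1], n, axis=0)
    t = np.linspace(0.0, s[-1], n, endpoint=not closed)
    out = np.empty((n, pts.shape[1]))
    for k in range(pts.shape[1]):
        out[:, k] = np.interp(t, s, pts[:, k])
    return out


# ---------------------------------------------------------------------------
# exact point -> triangle distance (Ericson, vectorized over pairs)


def closest_point_on_triangles(p: np.ndarray, a: np.ndarray, b: np.ndarray,
                               c: np.ndarray) -> np.ndarray:
    """Closest point to p on each triangle (a,b,c); all inputs (N,3)."""
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    m = (d1 <= 0) & (d2 <= 0)
    out[m] = a[m]
    done |= m

    m = ~done & (d3 >= 0) & (d4 <= d3)
    out[m] = b[m]
    done |= m

    vc = d1 * d4 - d3 * d2
    m = ~done & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
    out[m] = a[m] + v[m, None] * ab[m]
    done |= m

    m = ~done & (d6 >= 0) & (d5 <= d6)
    out[m] = c[m]
    done |= m

    vb = d5 * d2 - d1 * d6
    m = ~done & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
    out[m] = a[m] + w[m, None] * ac[m]
    done |= m

    va = d3 * d6 - d5 * d4
    m = ~done & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    denom = (d4 - d3) + (d5 - d6)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(denom != 0, (d4 - d3) / denom, 0.0)
    out[m] = b[m] + w[m, None] * (c[m] - b[m])
    done |= m

    m = ~done
    denom = va + vb + vc
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(denom != 0, vb / denom, 1.0 / 3.0)
        w = np.where(denom != 0, vc / denom, 1.0 / 3.0)
    out[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    return out


def nearest_on_surface(points: np.ndarray, vertices: np.ndarray,
                       faces: np.ndarray, k: int = 48):
    """Nearest point on a triangulated surface for each query point.

    KD-tree on triangle centroids proposes ``k`` candidate triangles per
    query; the exact minimum over candidates is returned. Returns
    ``(distances, closest_points)``.
    """
    cent = face_centroids(vertices, faces)
    k = min(k, len(faces))
    tree = cKDTree(cent)
    _, idx = tree.query(points, k=k)
    idx = np.atleast_2d(idx)
    npts = len(points)
    p_rep = np.repeat(points, k, axis=0)
    tri = faces[idx.ravel()]
    cp = closest_point_on_triangles(p_rep, vertices[tri[:, 0]],
                                    vertices[tri[:, 1]], vertices[tri[:, 2]])
    d = np.linalg.norm(cp - p_rep, axis=1).reshape(npts, k)
    best = d.argmin(axis=1)
    dist = d[np.arange(npts), best]
    closest = cp.reshape(npts, k, 3)[np.arange(npts), best]
    return dist, closest


# ---------------------------------------------------------------------------
# vertical ray casting (fixed -z direction)


def raycast_down(points: np.ndarray, vertices: np.ndarray, faces: np.ndarray):
    """Cast rays along -z from each point onto the surface.

    Returns ``(z_hit, hit_mask)`` where ``z_hit`` is the z of the highest
    intersection at or below the query point (the nearest along -z).
    Points whose (x, y) lie outside every triangle get ``hit_mask=False``.
    """
    tri = vertices[faces]  # (F,3,3)
    cent2 = tri[:, :, :2].mean(axis=1)
    rad = np.linalg.norm(tri[:, :, :2] - cent2[:, None, :], axis=2).max(axis=1)
    r_query = rad.max() * 1.0001 + 1e-9
    tree = cKDTree(cent2)
    z_hit = np.full(len(points), np.nan)
    hit = np.zeros(len(points), dtype=bool)
    neighbors = tree.query_ball_point(points[:, :2], r=r_query)
    for i, cand in enumerate(neighbors):
        if not cand:
            continue
        t = tri[cand]  # (C,3,3)
        x, y, z = points[i]
        a, b, c = t[:, 0], t[:, 1], t[:, 2]
        # 2D barycentric containment in the xy plane
        det = ((b[:, 1] - c[:, 1]) * (a[:, 0] - c[:, 0])
               + (c[:, 0] - b[:, 0]) * (a[:, 1] - c[:, 1]))
        ok = np.abs(det) > 1e-14
        with np.errstate(invalid="ignore", divide="ignore"):
            l1 = ((b[:, 1] - c[:, 1]) * (x - c[:, 0])
                  + (c[:, 0] - b[:, 0]) * (y - c[:, 1])) / det
            l2 = ((c[:, 1] - a[:, 1]) * (x - c[:, 0])
                  + (a[:, 0] - c[:, 0]) * (y - c[:, 1])) / det
        l3 = 1.0 - l1 - l2
        eps = 1e-9
        inside = ok & (l1 >= -eps) & (l2 >= -eps) & (l3 >= -eps)
        if not inside.any():
            continue
        zs = (l1 * a[:, 2] + l2 * b[:, 2] + l3 * c[:, 2])[inside]
        below = zs <= z + 1e-9
        z_hit[i] = zs[below].max() if below.any() else zs.min()
        hit[i] = True
    return z_hit, hit


# ---------------------------------------------------------------------------
# plane sections


def plane_section_loops(vertices: np.ndarray, faces: np.ndarray,
                        face_class: np.ndarray | None, x: float,
                        weld_tol: float = 1e-7):
    """Intersect the mesh with the plane x = const.

    Returns a list of ``(pts_yz, seg_class)`` per closed loop / open chain:
    ``pts_yz`` is (K,2) ordered (y, z); ``seg_class[i]`` labels the segment
    from point i to i+1 (class of the originating face, or -1 if unknown).
    """
    import trimesh.intersections as ti

    mesh = _as_trimesh(vertices, faces)
    out = ti.mesh_plane(mesh, plane_normal=np.array([1.0, 0, 0]),
                        plane_origin=np.array([x, 0.0, 0.0]),
                        return_faces=True)
    segments, fidx = out
    if len(segments) == 0:
        return []
    seg_cls = (face_class[fidx] if face_class is not None
               else np.full(len(fidx), -1))
    # weld endpoints
    pts = segments[:, :, 1:]  # (S,2,2) in (y,z)
    key = np.round(pts / weld_tol).astype(np.int64)
    flat = key.reshape(-1, 2)
    uniq, inv = np.unique(flat, axis=0, return_inverse=True)
    node_pos = np.zeros((len(uniq), 2))
    np.add.at(node_pos, inv, pts.reshape(-1, 2))
    cnt = np.bincount(inv, minlength=len(uniq)).astype(float)
    node_pos /= cnt[:, None]
    seg_nodes = inv.reshape(-1, 2)
    # drop zero-length segments
    keep = seg_nodes[:, 0] != seg_nodes[:, 1]
    seg_nodes, seg_cls = seg_nodes[keep], seg_cls[keep]
    if len(seg_nodes) == 0:
        return []
    cls_of = {tuple(sorted(sn)): int(c) for sn, c in zip(seg_nodes, seg_cls)}
    loops, chains = chain_edges(seg_nodes)
    result = []
    for path, closed in [(p, True) for p in loops] + [(p, False) for p in chains]:
        pp = node_pos[path]
        nseg = len(path) if closed else len(path) - 1
        scls = np.array([cls_of.get(tuple(sorted((int(path[i]),
                                                  int(path[(i + 1) % len(path)])))), -1)
                         for i in range(nseg)])
        result.append((pp, scls, closed))
    return result


def _as_trimesh(vertices, faces):
    import trimesh
    return trimesh.Trimesh(vertices=vertices, faces=faces, process=False)


def polygon_signed_area(pts2: np.ndarray) -> float:
    x, y = pts2[:, 0], pts2[:, 1]
    return float(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
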