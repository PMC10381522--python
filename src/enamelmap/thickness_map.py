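"""Topographic enamel-thickness mapping.

For every vertex of the outer enamel surface, the local enamel thickness
is taken as the unsigned distance to the nearest point on the EDJ face
set (cloud-to-mesh distance). The field can be exported as a color-coded
PLY model for visual inspection of the thickness distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _geometry as geom
from .cap_segmentation import EnamelCap
from .errors import DomainError
from .mesh_io import SurfaceMesh, save_ply_with_scalar


@dataclass
class ThicknessField:
    """Per-OES-vertex enamel thickness (mm) plus summary statistics."""

    vertex_ids: np.ndarray   # vertex indices (into the cap mesh) carrying values
    values: np.ndarray       # thickness per listed vertex, mm
    colormap: str = "viridis"

    def __post_init__(self):
        self.vertex_ids = np.asarray(self.vertex_ids, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.vertex_ids) != len(self.values):
            raise ValueError("vertex_ids and values length mismatch")
        if not np.isfinite(self.values).all() or (self.values < 0).any():
            raise DomainError("thickness values must be finite and >= 0")

    @property
    def stats(self) -> dict:
        v = self.values
        return {"min": float(v.min()), "max": float(v.max()),
                "mean": float(v.mean()), "median": float(np.median(v))}

    def dense(self, n_vertices: int, fill: float = 0.0) -> np.ndarray:
        out = np.full(n_vertices, fill)
        out[self.vertex_ids] = self.values
        return out

    def to_csv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.vertex_ids, self.values]),
                   delimiter=",", header="vertex_id,thickness_mm",
                   comments="", fmt=["%d", "%.9g"])


def thickness_field(cap: EnamelCap, method: str = "nearest") -> ThicknessField:
    """Enamel thickness at every OES vertex.

    ``method='nearest'`` (default): unsigned distance to the nearest point
    on the EDJ triangles — robust at sharp valleys and matching how
    cloud-to-mesh comparison tools map surface deviation.
    ``method='ray'``: distance along the inward vertex normal (always >=
    the nearest distance; can miss at grazing angles, where the nearest
    distance is substituted).
    """
    if len(cap.inner_faces) == 0:
        raise DomainError("cap has no EDJ faces")
    edj = cap.inner_submesh()
    vids = np.unique(cap.mesh.faces[cap.outer_faces])
    pts = cap.mesh.vertices[vids]
    dist, closest = geom.nearest_on_surface(pts, edj.vertices, edj.faces)
    if method == "nearest":
        values = dist
    elif method == "ray":
        normals = cap.mesh.vertex_normals()[vids]
        values = _ray_thickness(pts, normals, edj, fallback=dist)
    else:
        raise ValueError(f"unknown method {method!r}")
    return ThicknessField(vids, values)


def _ray_thickness(pts: np.ndarray, normals: np.ndarray, edj: SurfaceMesh,
                   fallback: np.ndarray) -> np.ndarray:
    """Distance along -normal to the EDJ (Moller-Trumbore over candidates)."""
    from scipy.spatial import cKDTree

    tri = edj.vertices[edj.faces]
    tree = cKDTree(geom.face_centroids(edj.vertices, edj.faces))
    k = min(64, len(edj.faces))
    _, cand = tree.query(pts, k=k)
    cand = np.atleast_2d(cand)
    out = fallback.copy()
    for i, (p, nrm) in enumerate(zip(pts, normals)):
        d = -nrm
        t = tri[cand[i]]
        e1, e2 = t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]
        h = np.cross(d, e2)
        a = np.einsum("ij,ij->i", e1, h)
        ok = np.abs(a) > 1e-12
        s = p - t[:, 0]
        with np.errstate(invalid="ignore", divide="ignore"):
            u = np.einsum("ij,ij->i", s, h) / a
            q = np.cross(s, e1)
            v = np.einsum("j,ij->i", d, q) / a
            tt = np.einsum("ij,ij->i", e2, q) / a
        ok &= (u >= -1e-9) & (v >= -1e-9) & (u + v <= 1 + 1e-9) & (tt > 0)
        if ok.any():
            out[i] = tt[ok].min()
    return out


def export_colored(mesh: SurfaceMesh, field: ThicknessField, path,
                   cmap: str = "viridis",
                   vrange: tuple[float, float] | None = None) -> None:
    """Write a PLY with the thickness as a `quality` scalar and RGB colors.

    The color range defaults to [0, 99th percentile] so isolated thick
    outliers do not wash out the map; values outside the range clamp to
    its endpoints. Vertices without a field value (EDJ side) are colored
    at the low end with thickness 0.
    """
    import matplotlib

    dense = field.dense(mesh.n_vertices, fill=0.0)
    if vrange is None:
        vrange = (0.0, float(np.percentile(field.values, 99)))
    lo, hi = vrange
    if hi <= lo:
        hi = lo + 1e-9
    t = np.clip((dense - lo) / (hi - lo), 0.0, 1.0)
    rgba = matplotlib.colormaps[cmap](t)
    colors = (rgba[:, :3] * 255).astype(np.uint8)
    save_ply_with_scalar(mesh, path, dense, colors)
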