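"""Enamel-cap surface segmentation.

An enamel cap scanned as a single triangulated shell contains two opposed
sheets: the outer enamel surface (OES) and the enamel-dentine junction
(EDJ), meeting at the thin cervical margin. Segmentation proceeds in two
passes:

1. every face is seeded *outer* or *inner* by the sign of
   ``dot(face normal, face centroid - mass centre)`` — an outward-facing
   face belongs to the OES;
2. the seed labels are refined by edge-connected components: the two
   dominant sheets are kept and every smaller component (misclassified
   basin patches, noise at the cervix where the radial direction
   degenerates) is absorbed into the neighbouring sheet with the longest
   shared border.

The cervical edge is then exactly the set of mesh edges bordered by one
outer and one inner face (or the mesh boundary rim for open-cap input).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from . import _geometry as geom
from .errors import (AmbiguousTopologyError, DegenerateInputError,
                     MultiLoopError, NoInternalSurfaceError)
from .mesh_io import SurfaceMesh

OUTER, INNER = 0, 1
_TIE_COSINE = 1e-3  # |cos| below this is deferred to the refinement pass


@dataclass
class Contour3D:
    """An ordered 3D polyline (mm), optionally closed."""

    points: np.ndarray
    closed: bool = True

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if len(self.points) >= 2:
            keep = np.ones(len(self.points), dtype=bool)
            d = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
            keep[1:] = d > 0
            self.points = self.points[keep]
        if self.closed and len(self.points) >= 2 and np.allclose(
                self.points[0], self.points[-1]):
            self.points = self.points[:-1]
        if self.closed and len(self.points) < 3:
            raise DegenerateInputError("closed contour needs >= 3 points")

    @property
    def length(self) -> float:
        return geom.polyline_length(self.points, closed=self.closed)

    def transformed(self, fn) -> "Contour3D":
        return Contour3D(fn(self.points), closed=self.closed)

    def to_csv(self, path) -> None:
        np.savetxt(path, self.points, delimiter=",", header="x,y,z",
                   comments="", fmt="%.9g")


@dataclass
class EnamelCap:
    """A segmented enamel-cap mesh: face partition + cervical edge."""

    mesh: SurfaceMesh
    outer_faces: np.ndarray  # face indices of the OES
    inner_faces: np.ndarray  # face indices of the EDJ
    cervical_edge: Contour3D | None = None
    mass_center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.outer_faces = np.asarray(self.outer_faces, dtype=np.int64)
        self.inner_faces = np.asarray(self.inner_faces, dtype=np.int64)
        n = self.mesh.n_faces
        both = np.zeros(n, dtype=np.int8)
        both[self.outer_faces] += 1
        both[self.inner_faces] += 1
        if (both != 1).any():
            raise DegenerateInputError(
                "outer/inner faces must partition the mesh faces")

    @property
    def face_class(self) -> np.ndarray:
        cls = np.full(self.mesh.n_faces, INNER, dtype=np.int8)
        cls[self.outer_faces] = OUTER
        return cls

    def outer_submesh(self) -> SurfaceMesh:
        return SurfaceMesh(self.mesh.vertices,
                           self.mesh.faces[self.outer_faces],
                           self.mesh.provenance + " [OES]")

    def inner_submesh(self) -> SurfaceMesh:
        return SurfaceMesh(self.mesh.vertices,
                           self.mesh.faces[self.inner_faces],
                           self.mesh.provenance + " [EDJ]")

    def transformed(self, fn) -> "EnamelCap":
        mesh = SurfaceMesh(fn(self.mesh.vertices), self.mesh.faces.copy(),
                           self.mesh.provenance)
        edge = self.cervical_edge.transformed(fn) if self.cervical_edge else None
        return EnamelCap(mesh, self.outer_faces.copy(),
                         self.inner_faces.copy(), edge,
                         fn(self.mass_center[None, :])[0])


def center_at_mass(mesh: SurfaceMesh):
    """Translate so the area-weighted surface centroid sits at the origin.

    Returns ``(centered_mesh, mass_center)`` with the original centroid.
    """
    if mesh.area <= 0:
        raise DegenerateInputError("mesh has zero total area")
    center = geom.area_centroid(mesh.vertices, mesh.faces)
    return mesh.translated(-center), center


def classify_surfaces(mesh: SurfaceMesh,
                      extract_edge: bool = True) -> EnamelCap:
    """Partition a two-sheet enamel-cap mesh into OES and EDJ faces."""
    center = geom.area_centroid(mesh.vertices, mesh.faces)
    normals = mesh.face_normals()
    radial = mesh.face_centroids() - center
    rn = np.linalg.norm(radial, axis=1)
    rn[rn == 0] = 1.0
    cosine = np.einsum("ij,ij->i", normals, radial) / rn
    seed = np.where(cosine >= 0, OUTER, INNER).astype(np.int8)
    tied = np.abs(cosine) < _TIE_COSINE

    labels = _refine_by_components(mesh, seed, tied)

    outer = np.flatnonzero(labels == OUTER)
    inner = np.flatnonzero(labels == INNER)
    if len(inner) == 0 or len(outer) == 0:
        raise NoInternalSurfaceError(
            "classification found a single surface class; the mesh has no "
            "internal (EDJ) sheet")
    cap = EnamelCap(mesh, outer, inner, None, center)
    if extract_edge:
        cap.cervical_edge = extract_cervical_edge(cap)
    return cap


def _refine_by_components(mesh: SurfaceMesh, seed: np.ndarray,
                          tied: np.ndarray) -> np.ndarray:
    tm = mesh.as_trimesh()
    adjacency = np.asarray(tm.face_adjacency)  # (A,2) face index pairs
    n = mesh.n_faces
    areas = mesh.face_areas()
    edge_len = (np.linalg.norm(
        mesh.vertices[tm.face_adjacency_edges[:, 0]]
        - mesh.vertices[tm.face_adjacency_edges[:, 1]], axis=1)
        if len(adjacency) else np.zeros(0))

    labels = seed.copy()
    # components of same-label faces (tied faces bond to either side)
    same = labels[adjacency[:, 0]] == labels[adjacency[:, 1]] if len(adjacency) \
        else np.zeros(0, dtype=bool)
    bond = same | tied[adjacency[:, 0]] | tied[adjacency[:, 1]] if len(adjacency) \
        else same
    g = coo_matrix((np.ones(int(bond.sum())),
                    (adjacency[bond, 0], adjacency[bond, 1])), shape=(n, n))
    n_comp, comp = connected_components(g, directed=False)
    comp_area = np.bincount(comp, weights=areas, minlength=n_comp)

    # majority label per component (area-weighted, tied faces excluded)
    comp_label = np.full(n_comp, -1, dtype=np.int8)
    for c in range(n_comp):
        m = (comp == c) & ~tied
        if not m.any():
            m = comp == c
        a_out = areas[m & (labels == OUTER)].sum()
        a_in = areas[m & (labels == INNER)].sum()
        comp_label[c] = OUTER if a_out >= a_in else INNER

    order = np.argsort(comp_area)[::-1]
    keep = set(order[:2].tolist())
    if n_comp >= 2 and comp_label[order[0]] == comp_label[order[1]]:
        # the two dominant sheets carry the same label: topology ambiguous
        sizes = sorted(comp_area, reverse=True)
        raise AmbiguousTopologyError(
            f"two dominant components share one class; component areas "
            f"{[round(s, 4) for s in sizes[:4]]}")

    # absorb every small component into the kept neighbour with the longest
    # shared border; isolated small components keep their majority label.
    if len(adjacency):
        for c in order[2:]:
            border = np.zeros(2)  # shared border length with kept comp 0 / 1
            for k, kc in enumerate(order[:2]):
                m = (((comp[adjacency[:, 0]] == c) & (comp[adjacency[:, 1]] == kc))
                     | ((comp[adjacency[:, 1]] == c) & (comp[adjacency[:, 0]] == kc)))
                border[k] = edge_len[m].sum()
            if border.max() > 0:
                comp_label[c] = comp_label[order[int(border.argmax())]]
    return comp_label[comp]


def extract_cervical_edge(cap: EnamelCap) -> Contour3D:
    """Ordered closed loop of vertices along the OES/EDJ border.

    For a closed cap this is the set of edges with one face of each class;
    for an open-rim model (surfaces not stitched) the mesh boundary loop is
    used instead. The loop is oriented counter-clockwise about +z.
    """
    cls = cap.face_class
    mesh = cap.mesh
    edges, inverse, counts = geom.unique_edges(mesh.faces)
    # a border edge is manifold (2 faces) with one face of each class
    face_of_edge = np.tile(np.arange(mesh.n_faces), 3)
    cls_sum = np.bincount(inverse, weights=cls[face_of_edge].astype(float),
                          minlength=len(edges))
    border = edges[(counts == 2) & (cls_sum == 1)]
    if len(border) == 0:
        loops = geom.boundary_loops(mesh.faces)
        if not loops:
            raise MultiLoopError("no class border and no boundary rim found")
        loops = [l for l in loops if len(l) >= 3]
        loops.sort(key=lambda l: -geom.polyline_length(mesh.vertices[l], True))
    else:
        loops, chains = geom.chain_edges(border)
        loops = [l for l in loops if len(l) >= 3]
        if not loops:
            raise MultiLoopError("cervical border edges do not form a loop")
        loops.sort(key=lambda l: -geom.polyline_length(mesh.vertices[l], True))
        # short parasitic loops (pits touching the border) are discarded
        main_len = geom.polyline_length(mesh.vertices[loops[0]], True)
        loops = [l for l in loops
                 if geom.polyline_length(mesh.vertices[l], True) >= 0.25 * main_len]
    if len(loops) > 1:
        lengths = [round(geom.polyline_length(mesh.vertices[l], True), 4)
                   for l in loops]
        raise MultiLoopError(f"multiple cervical-edge candidates; "
                             f"loop lengths {lengths}")
    loop = loops[0]
    pts = mesh.vertices[loop]
    # canonical traversal: counter-clockwise viewed from +z (occlusal side)
    if geom.polygon_signed_area(pts[:, :2]) < 0:
        loop = loop[::-1]
        pts = mesh.vertices[loop]
    # canonical start: lowest vertex index, for reproducibility
    start = int(np.argmin(loop))
    loop = np.roll(loop, -start)
    return Contour3D(mesh.vertices[loop], closed=True)


def export_labels_ply(cap: EnamelCap, path) -> None:
    """Write the cap with per-face class as a color-coded binary PLY."""
    tm = cap.mesh.as_trimesh()
    colors = np.zeros((cap.mesh.n_faces, 4), dtype=np.uint8)
    colors[cap.outer_faces] = (230, 200, 160, 255)  # enamel
    colors[cap.inner_faces] = (200, 120, 60, 255)   # dentine side
    tm.visual.face_colors = colors
    tm.export(str(path))
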