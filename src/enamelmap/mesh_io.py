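"""Reading, validating, repairing and writing triangulated surface meshes.

The universal carrier is :class:`SurfaceMesh`: vertices in mm, triangle
faces with consistent outward winding, plus a free-text provenance tag.
STL, PLY and OBJ are handled through :mod:`trimesh`; a small ASCII-PLY
writer/reader adds the per-vertex scalar + RGB properties used by the
topographic thickness maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from . import _geometry as geom
from .errors import DegenerateInputError, EmptyMeshError, FormatError, RepairError

_SUPPORTED = {".stl", ".ply", ".obj"}
_WELD_TOL = 1e-6  # mm; duplicate vertices are merged at this tolerance on load
_DEGENERATE_AREA = 1e-12  # mm^2


@dataclass
class SurfaceMesh:
    """A triangulated surface in mm."""

    vertices: np.ndarray
    faces: np.ndarray
    provenance: str = ""

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if not np.isfinite(self.vertices).all():
            raise DegenerateInputError("non-finite vertex coordinates")
        if len(self.faces) and self.faces.max() >= len(self.vertices):
            raise DegenerateInputError("face references out-of-range vertex index")

    # -- convenience -------------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def area(self) -> float:
        return geom.total_area(self.vertices, self.faces)

    def face_areas(self) -> np.ndarray:
        return geom.face_areas(self.vertices, self.faces)

    def face_normals(self) -> np.ndarray:
        return geom.face_normals(self.vertices, self.faces)

    def face_centroids(self) -> np.ndarray:
        return geom.face_centroids(self.vertices, self.faces)

    def vertex_normals(self) -> np.ndarray:
        return geom.vertex_normals(self.vertices, self.faces)

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices.copy(),
                               faces=self.faces.copy(), process=False)

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(self.vertices.copy(), self.faces.copy(), self.provenance)

    def translated(self, offset: np.ndarray) -> "SurfaceMesh":
        return SurfaceMesh(self.vertices + np.asarray(offset, float),
                           self.faces.copy(), self.provenance)


@dataclass
class ValidationReport:
    """Side-effect-free summary of mesh integrity."""

    watertight: bool
    n_boundary_loops: int
    area: float
    volume: float  # signed, divergence theorem
    n_vertices: int = 0
    n_faces: int = 0
    euler_characteristic: int = 0
    n_nonmanifold_edges: int = 0


def _weld(vertices: np.ndarray, faces: np.ndarray, tol: float = _WELD_TOL):
    key = np.round(vertices / tol).astype(np.int64)
    uniq, index, inverse = np.unique(key, axis=0, return_index=True,
                                     return_inverse=True)
    new_vertices = vertices[index]
    new_faces = inverse[faces]
    # drop faces that collapsed or duplicated
    ok = ((new_faces[:, 0] != new_faces[:, 1])
          & (new_faces[:, 1] != new_faces[:, 2])
          & (new_faces[:, 0] != new_faces[:, 2]))
    new_faces = new_faces[ok]
    areas = geom.face_areas(new_vertices, new_faces)
    new_faces = new_faces[areas > _DEGENERATE_AREA]
    return new_vertices, new_faces


def _orient_consistently(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Make winding consistent; outward defined by positive total signed volume.

    Nested closed components (an inner shell surface) are left pointing into
    the enclosed solid, i.e. their own signed contribution is negative.
    """
    tm = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    trimesh.repair.fix_normals(tm, multibody=True)
    faces = np.asarray(tm.faces)
    comps = trimesh.graph.connected_component_labels(tm.face_adjacency,
                                                     node_count=len(faces))
    n_comp = comps.max() + 1 if len(comps) else 0
    if n_comp <= 1:
        if geom.signed_volume(vertices, faces) < 0:
            faces = faces[:, ::-1]
        return faces
    # per component: fix_normals made each positively oriented; flip those
    # nested inside a larger component (centroid parity test).
    vols = np.array([abs(geom.signed_volume(vertices, faces[comps == c]))
                     for c in range(n_comp)])
    order = np.argsort(vols)[::-1]
    faces = faces.copy()
    for c in order[1:]:
        sub = faces[comps == c]
        centroid = geom.face_centroids(vertices, sub).mean(axis=0)
        outer = faces[comps == order[0]]
        z_hits, _ = _crossings_up(centroid, vertices, outer)
        if z_hits % 2 == 1:  # inside the largest component -> inner shell
            if geom.signed_volume(vertices, sub) > 0:
                faces[comps == c] = sub[:, ::-1]
        else:
            if geom.signed_volume(vertices, sub) < 0:
                faces[comps == c] = sub[:, ::-1]
    return faces


def _crossings_up(point: np.ndarray, vertices: np.ndarray, faces: np.ndarray):
    """Count intersections of an upward vertical ray with the surface."""
    tri = vertices[faces]
    x, y, z = point
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    det = ((b[:, 1] - c[:, 1]) * (a[:, 0] - c[:, 0])
           + (c[:, 0] - b[:, 0]) * (a[:, 1] - c[:, 1]))
    with np.errstate(invalid="ignore", divide="ignore"):
        l1 = ((b[:, 1] - c[:, 1]) * (x - c[:, 0])
              + (c[:, 0] - b[:, 0]) * (y - c[:, 1])) / det
        l2 = ((c[:, 1] - a[:, 1]) * (x - c[:, 0])
              + (a[:, 0] - c[:, 0]) * (y - c[:, 1])) / det
        l3 = 1.0 - l1 - l2
    inside = (np.abs(det) > 1e-14) & (l1 >= 0) & (l2 >= 0) & (l3 >= 0)
    zs = l1 * a[:, 2] + l2 * b[:, 2] + l3 * c[:, 2]
    above = inside & (zs > z)
    return int(above.sum()), zs[above]


def load_mesh(path, unit: str = "mm") -> SurfaceMesh:
    """Load an STL/PLY/OBJ surface mesh and express it in mm.

    ``unit='um'`` applies the micrometre-to-millimetre conversion (x 0.001)
    used when micro-CT exports carry micrometre coordinates. Duplicate
    vertices are welded at 1e-6 mm and winding is repaired so the total
    signed volume is non-negative.
    """
    path = Path(path)
    if unit not in ("mm", "um"):
        raise ValueError(f"unit must be 'mm' or 'um', got {unit!r}")
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if path.suffix.lower() not in _SUPPORTED:
        raise FormatError(f"unsupported mesh format: {path.suffix!r} "
                          f"(supported: {sorted(_SUPPORTED)})")
    try:
        tm = trimesh.load_mesh(str(path), process=False)
    except Exception as exc:  # pragma: no cover - backend specific
        raise FormatError(f"could not read {path}: {exc}") from exc
    if isinstance(tm, trimesh.Scene):
        geoms = list(tm.geometry.values())
        if not geoms:
            raise EmptyMeshError(f"{path} contains no mesh")
        tm = trimesh.util.concatenate(geoms)
    vertices = np.asarray(tm.vertices, dtype=np.float64)
    faces = np.asarray(tm.faces, dtype=np.int64)
    if len(vertices) == 0 or len(faces) == 0:
        raise EmptyMeshError(f"{path} contains no triangles")
    if unit == "um":
        vertices = vertices * 1e-3
    vertices, faces = _weld(vertices, faces)
    if len(faces) == 0:
        raise EmptyMeshError(f"{path}: all faces degenerate after welding")
    faces = _orient_consistently(vertices, faces)
    return SurfaceMesh(vertices, faces, provenance=f"{path.name} ({unit})")


def save_mesh(mesh: SurfaceMesh, path) -> None:
    """Write a mesh as STL, PLY or OBJ (chosen by extension)."""
    path = Path(path)
    if path.suffix.lower() not in _SUPPORTED:
        raise FormatError(f"unsupported output format: {path.suffix!r}")
    mesh.as_trimesh().export(str(path))


def validate(mesh: SurfaceMesh) -> ValidationReport:
    """Report watertightness, boundary loops, area and signed volume."""
    edges, _, counts = geom.unique_edges(mesh.faces)
    n_boundary = int((counts == 1).sum())
    loops = geom.boundary_loops(mesh.faces) if n_boundary else []
    nonmanifold = int((counts > 2).sum())
    # Euler characteristic over referenced vertices only
    v, e, f = len(np.unique(mesh.faces)), len(edges), mesh.n_faces
    return ValidationReport(
        watertight=(n_boundary == 0 and nonmanifold == 0),
        n_boundary_loops=len(loops),
        area=mesh.area,
        volume=geom.signed_volume(mesh.vertices, mesh.faces),
        n_vertices=mesh.n_vertices,
        n_faces=f,
        euler_characteristic=v - e + f,
        n_nonmanifold_edges=nonmanifold,
    )


def fill_holes(mesh: SurfaceMesh, max_perimeter: float | None = None):
    """Triangulate shut every boundary loop below a perimeter threshold.

    The default threshold is 10% of the bounding-box diagonal: it closes
    CT perforations and pits without sealing the cervical opening of a
    single-surface model. Returns ``(mesh, n_filled)``; existing faces are
    never removed. Loops above the threshold are left open.
    """
    _, _, counts = geom.unique_edges(mesh.faces)
    if (counts > 2).any():
        edges, _, c = geom.unique_edges(mesh.faces)
        bad = edges[c > 2][0]
        raise RepairError(f"non-manifold edge {tuple(bad)} (used by "
                          f"{int(c[c > 2][0])} faces); cannot repair")
    if max_perimeter is None:
        bbox = mesh.vertices.max(axis=0) - mesh.vertices.min(axis=0)
        max_perimeter = 0.10 * float(np.linalg.norm(bbox))
    loops = geom.boundary_loops(mesh.faces)
    if not loops:
        return mesh.copy(), 0
    new_vertices = [mesh.vertices]
    new_faces = [mesh.faces]
    next_idx = mesh.n_vertices
    n_filled = 0
    for loop in loops:
        pts = mesh.vertices[loop]
        perim = geom.polyline_length(pts, closed=True)
        if perim >= max_perimeter or len(loop) < 3:
            continue
        # loop orientation: boundary edges run opposite the adjacent face
        # winding, so fanning in loop order keeps the patch outward.
        loop = _orient_boundary_loop(mesh.faces, loop)
        center = pts.mean(axis=0)
        new_vertices.append(center[None, :])
        fan = np.array([[loop[i], loop[(i + 1) % len(loop)], next_idx]
                        for i in range(len(loop))])
        new_faces.append(fan)
        next_idx += 1
        n_filled += 1
    out = SurfaceMesh(np.vstack(new_vertices), np.vstack(new_faces),
                      mesh.provenance)
    return out, n_filled


def _orient_boundary_loop(faces: np.ndarray, loop: np.ndarray) -> np.ndarray:
    """Order a boundary loop so fan triangles match the mesh winding."""
    # directed boundary edge (a,b) appears in a face as (b,a): the hole patch
    # must traverse (a,b). Find the orientation of the first loop edge.
    a, b = int(loop[0]), int(loop[1])
    for f in faces:
        tri = [int(f[0]), int(f[1]), int(f[2])]
        for i in range(3):
            if tri[i] == b and tri[(i + 1) % 3] == a:
                return loop
            if tri[i] == a and tri[(i + 1) % 3] == b:
                return loop[::-1]
    return loop


# ---------------------------------------------------------------------------
# ASCII PLY with per-vertex scalar + color (topographic map export)


def save_ply_with_scalar(mesh: SurfaceMesh, path, scalar: np.ndarray,
                         colors: np.ndarray | None = None,
                         scalar_name: str = "quality") -> None:
    """Write an ASCII PLY with a per-vertex float property and optional RGB."""
    scalar = np.asarray(scalar, dtype=np.float64)
    if len(scalar) != mesh.n_vertices:
        raise ValueError("scalar length does not match vertex count")
    if colors is not None:
        colors = np.asarray(colors)
        if colors.shape != (mesh.n_vertices, 3):
            raise ValueError("colors must be (n_vertices, 3) uint8")
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {mesh.n_vertices}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write(f"property float {scalar_name}\n")
        if colors is not None:
            fh.write("property uchar red\nproperty uchar green\n"
                     "property uchar blue\n")
        fh.write(f"element face {mesh.n_faces}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for i in range(mesh.n_vertices):
            x, y, z = mesh.vertices[i]
            row = f"{x:.9g} {y:.9g} {z:.9g} {scalar[i]:.9g}"
            if colors is not None:
                r, g, b = colors[i]
                row += f" {int(r)} {int(g)} {int(b)}"
            fh.write(row + "\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def load_ply_scalar(path, scalar_name: str = "quality") -> np.ndarray:
    """Read back the per-vertex scalar written by :func:`save_ply_with_scalar`."""
    with open(path) as fh:
        line = fh.readline().strip()
        if line != "ply":
            raise FormatError(f"{path} is not a PLY file")
        n_vertex = 0
        props: list[str] = []
        in_vertex = False
        for line in fh:
            line = line.strip()
            if line.startswith("element vertex"):
                n_vertex = int(line.split()[-1])
                in_vertex = True
            elif line.startswith("element"):
                in_vertex = False
            elif line.startswith("property") and in_vertex:
                props.append(line.split()[-1])
            elif line == "end_header":
                break
        if scalar_name not in props:
            raise FormatError(f"no property {scalar_name!r} in {path}")
        col = props.index(scalar_name)
        out = np.empty(n_vertex)
        for i in range(n_vertex):
            out[i] = float(fh.readline().split()[col])
    return out


def convert(in_path, out_path, unit: str | None = None) -> SurfaceMesh:
    """Load (with unit conversion) and re-save a mesh; returns it.

    STL carries no units, so ``unit`` should always be given explicitly;
    when omitted, mm is assumed with a warning.
    """
    if unit is None:
        warnings.warn("no unit given; assuming input is already in mm",
                      stacklevel=2)
        unit = "mm"
    mesh = load_mesh(in_path, unit=unit)
    save_mesh(mesh, out_path)
    return mesh
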