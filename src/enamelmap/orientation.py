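"""Tooth coordinate frames built from the cervical edge.

The cervical margin is a curved, roughly planar ring; fitting a plane to
it (total least squares on arc-length-weighted edge points) yields the
occluso-cervical axis, with +z pointing toward the crown. The mesio-distal
axis is the major principal axis of the edge (optionally refined from the
occlusal contour), and the bucco-lingual axis completes a right-handed
orthonormal triad. The frame is intrinsic to the tooth: re-deriving it
after any rigid motion recovers the same canonical pose.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon, box

from . import _geometry as geom
from .cap_segmentation import Contour3D, EnamelCap
from .errors import DegenerateEdgeError, InsufficientContourError
from .mesh_io import SurfaceMesh

_AXIS_TIE_FRACTION = 0.01  # mesial/distal tie-break threshold on half areas


@dataclass
class ToothFrame:
    """Right-handed orthonormal tooth coordinate system.

    x: mesio-distal, y: bucco-lingual, z: occluso-cervical (+z occlusal).
    """

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def __post_init__(self):
        self.origin = np.asarray(self.origin, float).reshape(3)
        for name in ("x_axis", "y_axis", "z_axis"):
            v = np.asarray(getattr(self, name), float).reshape(3)
            setattr(self, name, v / np.linalg.norm(v))
        R = self.rotation
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValueError("frame axes are not orthonormal")
        if np.dot(np.cross(self.x_axis, self.y_axis), self.z_axis) < 0:
            raise ValueError("frame is left-handed")

    @property
    def rotation(self) -> np.ndarray:
        """World -> frame rotation; rows are the axes."""
        return np.vstack([self.x_axis, self.y_axis, self.z_axis])

    def to_frame(self, points: np.ndarray) -> np.ndarray:
        return (points - self.origin) @ self.rotation.T

    def from_frame(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation + self.origin

    @classmethod
    def identity(cls) -> "ToothFrame":
        return cls(np.zeros(3), [1, 0, 0], [0, 1, 0], [0, 0, 1])

    def is_identity(self, tol: float = 1e-9) -> bool:
        return (np.allclose(self.origin, 0, atol=tol)
                and np.allclose(self.rotation, np.eye(3), atol=tol))

    def to_json(self, path=None) -> str:
        payload = json.dumps({
            "origin": self.origin.tolist(),
            "x_axis": self.x_axis.tolist(),
            "y_axis": self.y_axis.tolist(),
            "z_axis": self.z_axis.tolist(),
        }, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, source) -> "ToothFrame":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            data = json.loads(source)
        else:
            with open(source) as fh:
                data = json.load(fh)
        return cls(np.array(data["origin"]), np.array(data["x_axis"]),
                   np.array(data["y_axis"]), np.array(data["z_axis"]))


def _arc_weights(points: np.ndarray, closed: bool) -> np.ndarray:
    """Per-point weights = half the length of the two adjacent segments."""
    n = len(points)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    if closed:
        seg = np.concatenate([seg, [np.linalg.norm(points[0] - points[-1])]])
        w = 0.5 * (seg + np.roll(seg, 1))
    else:
        w = np.zeros(n)
        w[:-1] += 0.5 * seg
        w[1:] += 0.5 * seg
    if w.sum() == 0:
        return np.full(n, 1.0 / n)
    return w / w.sum()


def _weighted_plane(points: np.ndarray, weights: np.ndarray):
    """TLS plane fit: returns (centroid, normal, in-plane major axis)."""
    c = (points * weights[:, None]).sum(axis=0)
    d = points - c
    cov = (d * weights[:, None]).T @ d
    evals, evecs = np.linalg.eigh(cov)  # ascending
    scale = np.linalg.norm(points.max(0) - points.min(0)) or 1.0
    if evals[1] < 1e-12 * scale ** 2:
        raise DegenerateEdgeError(
            "edge points are (near) collinear; plane fit is rank deficient")
    normal = evecs[:, 0]
    major = evecs[:, 2]
    return c, normal, major


def _orient_x_sign(points_2d: np.ndarray, origin_2d: np.ndarray,
                   x_dir_2d: np.ndarray, first_point_2d: np.ndarray):
    """Resolve the +-x ambiguity: toward the contour half with greater
    enclosed area; ties (<1%) resolved toward the first contour point."""
    poly = Polygon(points_2d)
    if not poly.is_valid:
        poly = poly.buffer(0)
    if poly.area > 0:
        # split by the line through the origin perpendicular to x
        span = 10.0 * max(np.abs(points_2d).max(), 1.0)
        # rotate so candidate x -> +u
        ux = x_dir_2d / np.linalg.norm(x_dir_2d)
        uy = np.array([-ux[1], ux[0]])
        R = np.vstack([ux, uy])
        local = (points_2d - origin_2d) @ R.T
        lpoly = Polygon(local)
        if not lpoly.is_valid:
            lpoly = lpoly.buffer(0)
        pos = lpoly.intersection(box(0, -span, span, span)).area
        neg = lpoly.intersection(box(-span, -span, 0, span)).area
        total = pos + neg
        if total > 0 and abs(pos - neg) / total > _AXIS_TIE_FRACTION:
            return 1.0 if pos >= neg else -1.0
    d = float(np.dot(x_dir_2d, first_point_2d - origin_2d))
    return 1.0 if d >= 0 else -1.0


def frame_from_cervical_edge(edge: Contour3D,
                             cap: EnamelCap | None = None) -> ToothFrame:
    """Preliminary tooth frame from the cervical-edge ring.

    origin: arc-length-weighted centroid of the edge points; z: TLS plane
    normal, signed toward the side holding the larger share of cap surface
    area (the crown); x: major principal axis of the edge projected into
    the plane; y = z cross x.
    """
    pts = edge.points
    if len(pts) < 10:
        raise DegenerateEdgeError(f"cervical edge has only {len(pts)} points")
    w = _arc_weights(pts, edge.closed)
    origin, normal, _ = _weighted_plane(pts, w)

    z = normal
    if cap is not None:
        areas = cap.mesh.face_areas()
        side = np.einsum("ij,j->i", cap.mesh.face_centroids() - origin, z)
        balance = float((areas * np.sign(side)).sum())
        if balance < 0:
            z = -z
    else:
        # no cap: canonical sign by the largest component
        k = int(np.argmax(np.abs(z)))
        if z[k] < 0:
            z = -z

    # in-plane principal axis of the edge
    d = pts - origin
    d_in = d - np.outer(d @ z, z)
    cov = (d_in * w[:, None]).T @ d_in
    evals, evecs = np.linalg.eigh(cov)
    x = evecs[:, 2]
    x = x - np.dot(x, z) * z
    x /= np.linalg.norm(x)
    y0 = np.cross(z, x)
    to2d = lambda p: np.column_stack([(p - origin) @ x, (p - origin) @ y0])
    sign = _orient_x_sign(to2d(pts), np.zeros(2), np.array([1.0, 0.0]),
                          to2d(pts[:1])[0])
    x = sign * x
    y = np.cross(z, x)
    return ToothFrame(origin, x, y, z)


def refine_frame_with_occlusal(frame: ToothFrame,
                               occlusal_contour: Contour3D) -> ToothFrame:
    """Re-align the mesio-distal axis to the occlusal contour.

    Keeps the origin and z axis; x becomes the major principal axis of the
    occlusal contour projected into the occlusal plane; re-orthonormalized.
    """
    pts = occlusal_contour.points
    if len(pts) < 10:
        raise InsufficientContourError(
            f"occlusal contour has only {len(pts)} points (need >= 10)")
    w = _arc_weights(pts, occlusal_contour.closed)
    z = frame.z_axis
    origin = frame.origin
    d = pts - (pts * w[:, None]).sum(axis=0)
    d_in = d - np.outer(d @ z, z)
    cov = (d_in * w[:, None]).T @ d_in
    evals, evecs = np.linalg.eigh(cov)
    scale = np.linalg.norm(pts.max(0) - pts.min(0)) or 1.0
    if evals[2] < 1e-12 * scale ** 2:
        raise InsufficientContourError("occlusal contour is degenerate")
    x = evecs[:, 2]
    x = x - np.dot(x, z) * z
    x /= np.linalg.norm(x)
    y0 = np.cross(z, x)
    center2 = (pts * w[:, None]).sum(axis=0)
    to2d = lambda p: np.column_stack([(p - center2) @ x, (p - center2) @ y0])
    sign = _orient_x_sign(to2d(pts), np.zeros(2), np.array([1.0, 0.0]),
                          to2d(pts[:1])[0])
    x = sign * x
    y = np.cross(z, x)
    return ToothFrame(origin, x, y, z)


def apply_frame(mesh: SurfaceMesh, frame: ToothFrame) -> SurfaceMesh:
    """Rigid transform of a mesh into frame coordinates."""
    return SurfaceMesh(frame.to_frame(mesh.vertices), mesh.faces.copy(),
                       mesh.provenance)


def apply_frame_to_cap(cap: EnamelCap, frame: ToothFrame) -> EnamelCap:
    return cap.transformed(frame.to_frame)
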