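"""Sector segmentation and the average enamel-thickness parameters.

The occlusal surface (bounded by the occlusal contour) is split by the
mesio-distal midline into the inner slope of the buccal cusp and the
inner slope of the lingual cusp. Per sector, the 3D average enamel
thickness uses a symmetrized denominator:

    SAET3D = SV / SAA,      SAA = (SAedj + SAoes) / 2

where SV is the sector enamel volume and SAedj / SAoes the sector's EDJ
and outer-enamel surface areas. The planar analogue on a bucco-lingual
section is

    SAET2D = SA / SACL,     SACL = (SCLedj + SCLoes) / 2

with the sector cross-section area SA and the two contour lengths.
Averaging the two bounding surfaces (rather than the classical EDJ-only
denominator) compensates for the non-developable, doubly bounded shape
of a worn enamel cap; for a thin shell of uniform thickness t both
parameters converge to t.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from shapely import contains_xy
from shapely.geometry import Polygon

from . import _geometry as geom
from .cap_segmentation import Contour3D, EnamelCap, INNER, OUTER
from .errors import DomainError, ReportError, SegmentationError
from .occlusal_topography import PlanarSection

OCCLUSAL = "occlusal_total"
BUCCAL = "buccal_inner_slope"
LINGUAL = "lingual_inner_slope"
SECTOR_IDS = (OCCLUSAL, BUCCAL, LINGUAL)


@dataclass
class SectorMeasurement3D:
    """Volumetric sector measurement; SAA and SAET3D are exact by identity."""

    sector_id: str
    SV: float      # enamel volume, mm^3
    SAedj: float   # EDJ area, mm^2
    SAoes: float   # OES area, mm^2

    def __post_init__(self):
        for name in ("SV", "SAedj", "SAoes"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise DomainError(f"{name} must be positive, got {v}")

    @property
    def SAA(self) -> float:
        return (self.SAedj + self.SAoes) / 2.0

    @property
    def SAET3D(self) -> float:
        return self.SV / self.SAA

    def aet_classical(self) -> float:
        """Classical average enamel thickness (EDJ-only denominator)."""
        return self.SV / self.SAedj


@dataclass
class SectorMeasurement2D:
    """Planar sector measurement; SACL and SAET2D are exact by identity."""

    sector_id: str
    SA: float       # enamel cross-section area, mm^2
    SCLoes: float   # outer-enamel contour length, mm
    SCLedj: float   # EDJ contour length, mm

    def __post_init__(self):
        for name in ("SA", "SCLoes", "SCLedj"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 1e-9):
                raise DomainError(f"{name} must be positive, got {v}")

    @property
    def SACL(self) -> float:
        return (self.SCLedj + self.SCLoes) / 2.0

    @property
    def SAET2D(self) -> float:
        return self.SA / self.SACL


def saet3d(SV: float, SAedj: float, SAoes: float,
           sector_id: str = OCCLUSAL) -> SectorMeasurement3D:
    """Package SV/SAedj/SAoes into a 3D measurement (inputs must be > 0)."""
    return SectorMeasurement3D(sector_id, float(SV), float(SAedj), float(SAoes))


def saet2d(oes_chain: np.ndarray, edj_chain: np.ndarray,
           sector_id: str = OCCLUSAL) -> SectorMeasurement2D:
    """Planar sector measurement from corresponding OES and EDJ chains.

    Chains are ordered (y, z) polylines spanning the same sector; the
    sector polygon is the OES chain joined to the reversed EDJ chain with
    straight closing cuts at both ends.
    """
    oes_chain = np.asarray(oes_chain, float).reshape(-1, 2)
    edj_chain = np.asarray(edj_chain, float).reshape(-1, 2)
    if len(oes_chain) < 2 or len(edj_chain) < 2:
        raise DomainError("chains need at least 2 points each")
    # orient consistently (both increasing in y) before closing the polygon
    if oes_chain[0, 0] > oes_chain[-1, 0]:
        oes_chain = oes_chain[::-1]
    if edj_chain[0, 0] > edj_chain[-1, 0]:
        edj_chain = edj_chain[::-1]
    poly = Polygon(np.vstack([oes_chain, edj_chain[::-1]]))
    if not poly.is_valid:
        poly = poly.buffer(0)
    sa = float(poly.area)
    return SectorMeasurement2D(sector_id, sa,
                               geom.polyline_length(oes_chain),
                               geom.polyline_length(edj_chain))


# ---------------------------------------------------------------------------
# sector patches on the mesh


@dataclass
class SectorPatches:
    """Per-sector face-index subsets of the OES and the EDJ."""

    oes: dict = field(default_factory=dict)  # sector_id -> face indices
    edj: dict = field(default_factory=dict)


def _poly_of(contour: Contour3D) -> Polygon:
    poly = Polygon(contour.points[:, :2])
    if not poly.is_valid:
        poly = poly.buffer(0)
    return poly


def _midline_y_at(midline: Contour3D, x: np.ndarray) -> np.ndarray:
    pts = midline.points[np.argsort(midline.points[:, 0])]
    return np.interp(x, pts[:, 0], pts[:, 1])


def segment_sectors(cap: EnamelCap, occlusal_oes: Contour3D,
                    occlusal_edj: Contour3D, midline_oes: Contour3D,
                    midline_edj: Contour3D) -> SectorPatches:
    """Split the occlusal OES and EDJ face sets by the midline.

    Faces are attributed whole, by centroid: inside the (projected)
    occlusal contour, buccal where the centroid lies on the +y side of
    the midline at its x position, lingual on the -y side. This keeps
    the sectors an exact partition of the occlusal total.
    """
    if not occlusal_oes.closed or not occlusal_edj.closed:
        raise SegmentationError("occlusal contours must be closed loops")
    for mid in (midline_oes, midline_edj):
        xs = mid.points[:, 0]
        if not (np.diff(np.sort(xs)) >= 0).all():
            raise SegmentationError("midline must be x-monotone")

    patches = SectorPatches()
    for cls_faces, contour, midline, store in (
            (cap.outer_faces, occlusal_oes, midline_oes, patches.oes),
            (cap.inner_faces, occlusal_edj, midline_edj, patches.edj)):
        cent = geom.face_centroids(cap.mesh.vertices, cap.mesh.faces[cls_faces])
        inside = contains_xy(_poly_of(contour), cent[:, 0], cent[:, 1])
        occl = cls_faces[inside]
        if len(occl) == 0:
            raise SegmentationError("no faces inside the occlusal contour")
        c_in = cent[inside]
        y_mid = _midline_y_at(midline, c_in[:, 0])
        store[OCCLUSAL] = occl
        store[BUCCAL] = occl[c_in[:, 1] > y_mid]
        store[LINGUAL] = occl[c_in[:, 1] <= y_mid]
    return patches


def patch_area(mesh, faces: np.ndarray) -> float:
    """Total triangle area of a face subset (mm^2)."""
    faces = np.asarray(faces, dtype=np.int64)
    if len(faces) == 0:
        warnings.warn("empty patch; area = 0", stacklevel=2)
        return 0.0
    return float(geom.face_areas(mesh.vertices, mesh.faces[faces]).sum())


def sector_volume(cap: EnamelCap, oes_faces: np.ndarray,
                  _nearest_cache: dict | None = None) -> float:
    """Enamel volume under an OES patch (mm^3).

    Each OES triangle is extruded to the nearest points of its vertices on
    the EDJ surface, forming a triangular prism decomposed into three
    tetrahedra. The per-face sum is exactly additive over disjoint patches
    and converges to the volume of the enamel shell between the surfaces.
    """
    oes_faces = np.asarray(oes_faces, dtype=np.int64)
    if len(oes_faces) == 0:
        warnings.warn("empty patch; volume = 0", stacklevel=2)
        return 0.0
    mesh = cap.mesh
    vids = np.unique(mesh.faces[oes_faces])
    if _nearest_cache is not None and "map" in _nearest_cache:
        vmap = _nearest_cache["map"]
        missing = vids[~np.isin(vids, _nearest_cache["ids"])]
    else:
        vmap, missing = {}, vids
    if len(missing):
        edj = cap.inner_submesh()
        _, closest = geom.nearest_on_surface(mesh.vertices[missing],
                                             edj.vertices, edj.faces)
        for vid, q in zip(missing, closest):
            vmap[int(vid)] = q
        if _nearest_cache is not None:
            _nearest_cache["map"] = vmap
            _nearest_cache["ids"] = np.array(sorted(vmap.keys()))
    tri = mesh.faces[oes_faces]
    P = mesh.vertices[tri]                                   # (F,3,3)
    Q = np.stack([[vmap[int(v)] for v in f] for f in tri])   # (F,3,3)

    def tet(a, b, c, d):
        return np.einsum("ij,ij->i", a - d, np.cross(b - d, c - d)) / 6.0

    v = (tet(P[:, 0], P[:, 1], P[:, 2], Q[:, 0])
         + tet(P[:, 1], P[:, 2], Q[:, 0], Q[:, 1])
         + tet(P[:, 2], Q[:, 0], Q[:, 1], Q[:, 2]))
    return float(abs(v.sum()))


def measure_sectors(cap: EnamelCap, patches: SectorPatches) -> dict:
    """SectorMeasurement3D for the occlusal total and both inner slopes."""
    cache: dict = {}
    out = {}
    for sid in SECTOR_IDS:
        out[sid] = SectorMeasurement3D(
            sid,
            SV=sector_volume(cap, patches.oes[sid], cache),
            SAedj=patch_area(cap.mesh, patches.edj[sid]),
            SAoes=patch_area(cap.mesh, patches.oes[sid]),
        )
    return out


# ---------------------------------------------------------------------------
# planar sector measurement on a section


def _clip_chain_y(chain: np.ndarray, y0: float, y1: float):
    """Sub-chains of a (y, z) polyline clipped to y in [y0, y1]."""
    pieces, cur = [], []
    for k in range(len(chain) - 1):
        p, q = chain[k], chain[k + 1]
        seg = _clip_segment_y(p, q, y0, y1)
        if seg is None:
            if len(cur) >= 2:
                pieces.append(np.array(cur))
            cur = []
            continue
        a, b = seg
        if not cur or not np.allclose(cur[-1], a):
            if len(cur) >= 2:
                pieces.append(np.array(cur))
            cur = [a]
        cur.append(b)
    if len(cur) >= 2:
        pieces.append(np.array(cur))
    return pieces


def _clip_segment_y(p, q, y0, y1):
    (ya, za), (yb, zb) = p, q
    if ya > yb:
        (ya, za), (yb, zb) = (yb, zb), (ya, za)
        flipped = True
    else:
        flipped = False
    if yb < y0 or ya > y1:
        return None
    z_at = lambda y: za + (zb - za) * ((y - ya) / (yb - ya)) if yb > ya else za
    a = np.array([max(ya, y0), z_at(max(ya, y0))])
    b = np.array([min(yb, y1), z_at(min(yb, y1))])
    if a[0] >= b[0]:
        return None
    return (b, a) if flipped else (a, b)


def _sector_chain(section: PlanarSection, cls: int, y0: float, y1: float):
    """Topmost class chain of the section clipped to [y0, y1], joined."""
    pieces = []
    for chain in section.class_chains(cls):
        pieces.extend(_clip_chain_y(chain, y0, y1))
    if not pieces:
        return None
    # keep upper-envelope pieces: when pieces overlap in y, prefer higher z
    pieces.sort(key=lambda c: -float(np.mean(c[:, 1])))
    kept, cover = [], []
    for c in pieces:
        lo, hi = float(c[:, 0].min()), float(c[:, 0].max())
        if any(lo >= a - 1e-9 and hi <= b + 1e-9 for a, b in cover):
            continue
        kept.append(c)
        cover.append((lo, hi))
    kept.sort(key=lambda c: float(c[:, 0].min()))
    return np.vstack(kept)


def measure_section_2d(section: PlanarSection, window: tuple[float, float],
                       midline_y: float) -> dict:
    """2D sector measurements of one bucco-lingual section.

    ``window`` is the occlusal bucco-lingual range (lingual bound,
    buccal bound); ``midline_y`` splits it. Returns measurements for the
    occlusal total and both slopes (sectors whose chains degenerate are
    omitted).
    """
    y0, y1 = window
    out = {}
    for sid, (a, b) in ((OCCLUSAL, (y0, y1)), (BUCCAL, (midline_y, y1)),
                        (LINGUAL, (y0, midline_y))):
        oes = _sector_chain(section, OUTER, a, b)
        edj = _sector_chain(section, INNER, a, b)
        if oes is None or edj is None:
            continue
        try:
            out[sid] = saet2d(oes, edj, sid)
        except DomainError:
            continue
    return out


# ---------------------------------------------------------------------------
# report


def _round2(value: float) -> float:
    return float(Decimal(repr(value)).quantize(Decimal("0.01"),
                                               rounding=ROUND_HALF_UP))


@dataclass
class ToothReport:
    """Per-tooth measurement table with percentage-of-segment analysis.

    Mirrors the canonical layout: rows = OES area, EDJ area, enamel
    volume, SAET3D; columns = occlusal total, inner buccal slope, inner
    lingual slope; percentages are each sector's share of the occlusal
    total (thickness relative to the occlusal SAET3D), rounded half-up to
    2 decimals.
    """

    label: str
    measurements: dict  # sector_id -> SectorMeasurement3D
    thickness_values: dict | None = None  # optional explicit SAET3D row
    percentages: dict = field(default_factory=dict)
    consistent: bool = True  # buccal% + lingual% = 100 +- 0.01 for extensive rows

    ROWS = ("SAoes", "SAedj", "SV", "SAET3D")

    def __post_init__(self):
        if set(self.measurements) != set(SECTOR_IDS):
            raise ReportError(f"need sectors {SECTOR_IDS}, got "
                              f"{sorted(self.measurements)}")
        self.percentages = {}
        for row in self.ROWS:
            vals = {sid: self._row_value(row, sid) for sid in SECTOR_IDS}
            total = vals[OCCLUSAL]
            self.percentages[row] = {
                sid: _round2(100.0 * vals[sid] / total) for sid in SECTOR_IDS}
        self.consistent = all(
            abs(self.percentages[row][BUCCAL] + self.percentages[row][LINGUAL]
                - 100.0) <= 0.01 + 1e-9
            for row in ("SAoes", "SAedj", "SV"))

    def _row_value(self, row: str, sid: str) -> float:
        if row == "SAET3D" and self.thickness_values is not None:
            return float(self.thickness_values[sid])
        return getattr(self.measurements[sid], row)

    def to_dict(self) -> dict:
        def fmt(x):
            return float(f"{x:.6g}")
        return {
            "label": self.label,
            "sectors": {
                sid: {
                    "SAoes_mm2": fmt(m.SAoes), "SAedj_mm2": fmt(m.SAedj),
                    "SV_mm3": fmt(m.SV), "SAA_mm2": fmt(m.SAA),
                    "SAET3D_mm": fmt(m.SAET3D),
                } for sid, m in self.measurements.items()},
            "percent_of_segment": self.percentages,
            "consistent": self.consistent,
        }

    def to_json(self, path=None) -> str:
        payload = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    def to_frame(self):
        """Table-layout pandas DataFrame (rows x sectors, values + %)."""
        import pandas as pd

        rows = []
        names = {"SAoes": "Outer enamel surface area, mm2",
                 "SAedj": "Enamel-dentine junction area, mm2",
                 "SV": "Enamel volume, mm3",
                 "SAET3D": "Three-dimensional average enamel thickness, mm"}
        secs = {OCCLUSAL: "Occlusal surface",
                BUCCAL: "Inner slope of buccal cusp",
                LINGUAL: "Inner slope of lingual cusp"}
        for row in self.ROWS:
            for sid in SECTOR_IDS:
                rows.append({
                    "quantity": names[row], "sector": secs[sid],
                    "value": self._row_value(row, sid),
                    "percent_of_segment": self.percentages[row][sid],
                })
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6g")


def build_report(occlusal: SectorMeasurement3D, buccal: SectorMeasurement3D,
                 lingual: SectorMeasurement3D, label: str = "",
                 thickness_values: tuple[float, float, float] | None = None
                 ) -> ToothReport:
    """Assemble the per-tooth report with percentage-of-segment columns.

    ``thickness_values`` optionally supplies the SAET3D row explicitly
    (occlusal, buccal, lingual) — e.g. externally reported thicknesses —
    instead of deriving it from SV/SAA.
    """
    for m, sid in ((occlusal, OCCLUSAL), (buccal, BUCCAL), (lingual, LINGUAL)):
        if m.sector_id != sid:
            m = SectorMeasurement3D(sid, m.SV, m.SAedj, m.SAoes)
        if sid == OCCLUSAL:
            occlusal = m
        elif sid == BUCCAL:
            buccal = m
        else:
            lingual = m
    tv = None
    if thickness_values is not None:
        tv = dict(zip(SECTOR_IDS, thickness_values))
    return ToothReport(label, {OCCLUSAL: occlusal, BUCCAL: buccal,
                               LINGUAL: lingual}, thickness_values=tv)
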