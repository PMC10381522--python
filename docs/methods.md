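# Methods

This note documents the models, algorithms and numerical choices behind
`enamelmap`, and what the synthetic fixtures do and do not establish
about behaviour on real scan data.

## Input model and units

The pipeline starts from a triangulated surface of a tooth's enamel cap
containing both the outer enamel surface (OES) and the enamel–dentine
junction (EDJ), meeting at the cervical margin — the standard product of
micro-CT segmentation after meshing. All computation is in millimetres;
µm input is scaled by 10⁻³ on load. STL is triangle soup, so duplicate
vertices are welded at 10⁻⁶ mm before any topology query; winding is
made consistent by propagation, with "outward" fixed by a non-negative
total signed volume (nested closed components, i.e. inner shell walls,
are oriented into the solid via a ray-parity containment test).
Perforations are closed before analysis by fan-triangulating boundary
loops whose perimeter is below a threshold, default 10% of the
bounding-box diagonal — small enough to leave the cervical opening of a
single-surface model untouched. Note that a punched hole's boundary is
jagged: its perimeter can be ~1.5× the circumference of the removed
disk, which matters when choosing an explicit threshold.

## OES/EDJ segmentation

Faces are seeded by the sign of `dot(face normal, centroid − mass
centre)` — outward-facing faces are enamel-side. The seed is exact on
convex regions but fails systematically where the radial direction
degenerates (under the occlusal basin, at the cervix). A refinement pass
therefore takes edge-connected components of equal-label faces, keeps
the two dominant sheets, and absorbs every smaller component into the
kept neighbour with the longest shared border; near-tangential faces
(|cos| < 10⁻³) bond to either side and are resolved by their component.
If the two largest components carry the same label the topology is
reported as ambiguous rather than guessed. Classification is per-face;
the cervical edge is then *exactly* the set of manifold edges with one
face of each class, chained into a loop, oriented counter-clockwise
about +z, with a deterministic start (lowest vertex index). Parasitic
loops shorter than 25% of the longest candidate are discarded; several
surviving loops are an error, not a guess.

## Tooth frame

The cervical margin is approximately planar and intrinsic to the tooth,
so the frame derives from it alone: origin = arc-length-weighted
centroid of the edge points (weighting makes the result independent of
vertex spacing); z = total-least-squares plane normal (smallest
eigenvector of the weighted second-moment tensor), signed toward the
side carrying the larger share of cap area (the crown); x = major
in-plane principal axis, refined afterwards to the principal axis of the
occlusal contour; y = z × x. The ±x ambiguity is resolved toward the
contour half with the greater enclosed area; if the halves differ by
less than 1% (symmetric crowns), a deterministic tie-break points +x
toward the first contour point. True mesial/distal labelling is user
metadata — the tie-break only guarantees reproducibility, including
recovery of the canonical pose to 10⁻⁶ mm after arbitrary rigid motion.
A frame-override file takes precedence over both steps.

## Curvature and the occlusal contour

Per-vertex mean curvature uses the cotangent Laplacian with Meyer mixed
(Voronoi) areas; barycentric areas were tried first and leave ~15%
error at irregular-valence vertices, vs ≲1% with mixed areas on
analytic spheres and cylinders. Sign convention: convex (cusp-like)
positive. Boundary vertices are flagged and excluded.

The occlusal contour is a closed crest cycle on the OES. A radial sweep
about the crown axis (96 azimuth bins around the two cusp apices'
centroid) proposes the highest OES vertex per bin; consecutive proposals
are joined by Dijkstra paths with edge cost `length / (ε + max(0, κ))`,
ε = 10⁻³ mm⁻¹. Two guards keep the path on the marginal/cusp ridges:
the search graph is restricted to a crest band (vertices no lower than
the lowest sweep pick minus 10% of the crown relief), and κ is clipped
at its 90th percentile so that isolated convexity spikes — pit rims,
mesh noise — cannot out-attract the genuine ridge (without the clip,
paths on pitted crowns detour wildly along pit rims). Retraced spurs
from path stitching are collapsed to a fixpoint. The result must
enclose both cusp apices (checked with a two-edge-length buffer, since
the crest passes through the apices themselves). User override points
are snapped to OES vertices and joined along plain geodesics instead.

Contours are transferred to the EDJ by casting each point along −z and
taking the nearest intersection; isolated misses are interpolated from
neighbours (circularly for closed contours) and more than 20% misses
abort the projection. Because both the occlusal contour (on the crest)
and the midline (in the valley) lie on near-horizontal parts of the
surface, vertical projection and normal projection nearly coincide
there, which keeps the EDJ sector boundaries consistent with the OES
ones.

## Sections and midline

Bucco–lingual sections are mesh–plane intersections at n positions
(default 80, matching established practice for setting the midline)
uniformly spaced at fractions i/(n+1) of the occlusal contour's
mesio-distal extent (configurable to the whole crown). Intersection
segments inherit the face class, are welded at endpoints and chained
into loops; each section therefore knows its OES and EDJ sub-chains.

The midline is the per-section deepest OES point: the minimal-z chain
point whose y lies within the occlusal contour's bucco–lingual window at
that section. Ties (Δz < 10⁻⁶ mm) go to the candidate nearest the
previous section's midline y (first section: nearest y = 0) —
continuity mirrors the manual corrections this step classically needs at
pits. The optional pit filter drops candidates whose mapped vertex
curvature lies below the 1st percentile of the OES curvature
distribution: pit walls and floors are far more concave than the
developmental groove, so the filter removes them while at worst shifting
the pick by the width of the excluded strip (well under the two-edge
tolerance used in validation). Per-section overrides replace automatic
points verbatim. The result is an open, x-monotone polyline.

## Sector metrics

Sector patches are face subsets: OES faces with centroid inside the
occlusal contour (xy projection), split buccal/lingual by the midline's
interpolated y at the centroid's x; likewise on the EDJ with the
projected contours. Faces straddling a boundary are attributed whole by
centroid rather than cut: the attribution error is O(edge length),
symmetric on both sides, and in exchange the three sectors are an exact
partition — areas and volumes are additive to machine precision, which
is asserted on every run rather than trusted.

Sector volume is a per-face prism sum: each OES triangle is extruded to
the nearest points of its vertices on the EDJ surface and decomposed
into three tetrahedra. This is exactly additive over disjoint patches,
has no wall-construction failure modes, and converges to the
offset-shell volume: on a concentric sphere shell (R = 1.1, r = 1.0,
~26k faces) the measured SAET3D is within 0.14% of the closed form
(2/3)(R³−r³)/(R²+r²) ≈ 0.09985. A ruled-side-wall closure between
boundary contours was considered and rejected: matching two jagged
patch boundaries leaks volume at exactly the accuracy level the
additivity check is meant to protect.

SAA = (SAedj+SAoes)/2 and SAET3D = SV/SAA are exact identities of their
inputs (property-tested against independent recomputation), as are SACL
and SAET2D. In 2D, the sector polygon is the OES chain joined to the
reversed EDJ chain with straight closing cuts; a rectangular band of
width 10 and thickness 0.5 returns SAET2D = 0.5 to 10⁻⁹, and on a
prismatic (extruded) fixture the mean sectional SAET2D matches SAET3D
to ~2·10⁻⁶ relative.

The report mirrors the standard table layout — OES area, EDJ area,
volume, SAET3D × (occlusal, buccal slope, lingual slope) — with
percentage-of-segment columns rounded half-up to 2 decimals. The
SAET3D row can be supplied explicitly (e.g. an externally published
thickness row) instead of being derived from SV/SAA. Percentage
consistency (buccal + lingual = 100.00 ± 0.01 for the extensive rows)
is reported as a flag, not enforced: externally printed tables can
violate it through independent rounding of their inputs. The classical
EDJ-only denominator remains available (`aet_classical`) for
comparison, not as the default.

## Thickness mapping

Per-OES-vertex thickness is the unsigned distance to the nearest point
on the EDJ triangles (KD-tree candidates + exact point–triangle
distance), the same definition used by cloud-to-mesh comparison tools
and robust at sharp dentine horns; a normal-ray variant (`method='ray'`,
always ≥ the nearest distance) is available. Colored PLY export uses a
perceptually uniform colormap over [0, 99th percentile] by default so a
few thick outliers do not wash out the map; out-of-range values clamp.

## Synthetic fixtures: what they emulate and what they don't

`synthetic_tooth` generates offset shells with known truth: concentric
icospheres (closed-form areas/volume/thickness), an open hemispherical
cup with a stitched cervical band (exact rim circumference 2πr for the
class border), a prismatic enamel band, and a two-cusp crown. The crown
is a height field over an 11 × 9.5 mm elliptical footprint — roughly a
great-ape lower molar — with two Gaussian cusps at y = ±2.9 mm,
mesial/distal marginal ridges, a central developmental groove along
y = 0 (which makes y = 0 the strict bucco–lingual minimum of every
occlusal section, as on a real crown the central groove does), ~3 mm of
relief and a cervix at z = 0. The EDJ is the inward offset along
analytic surface normals, so uniform thickness is true by construction;
a screen rejects thicknesses exceeding 90% of the minimal convex radius
of curvature, where the offset would self-intersect. Wear is a planar
truncation of both sheets (reporting exposed-dentine vertices); pits are
crater depressions (they mislead a naive deepest-point search, which is
the point); perforations are punched holes (exercising repair). All
randomness hangs off one seed; the same spec reproduces vertex arrays
bitwise.

These fixtures establish correctness of the geometry pipeline, not
robustness to everything real scans do: they have no segmentation noise,
no non-uniform "real" enamel distribution, no chipped cervical margins,
single-rooted two-cusp topology only, and their pits are smooth craters
rather than irregular taphonomic damage. Results on real material
should lean on the override mechanism exactly as semi-automated
practice does.

## Numerical choices and problem sizes

Default fixture resolution is 0.25 mm target edge length (~11k faces
per crown), sphere shells use icosphere subdivision 4–5 (~10–26k
faces), and validation runs 80 sections — sizes at which every
documented tolerance holds with margin while the full pipeline completes
in about a second. Key tolerances: vertex weld 10⁻⁶ mm; degenerate-face
area 10⁻¹² mm²; classification tie cosine 10⁻³; ridge-cost ε 10⁻³
mm⁻¹ with 90th-percentile κ clip; midline tie window 10⁻⁶ mm; pit
percentile 1; projection failure above 20% misses; report rounding
half-up at 2 decimals; report floats at 6 significant digits for
byte-stable re-runs.

## Known limitations

* Sectioning of published specimens was reported in 3D mode only; the
  2D apparatus here generalises it and is validated on prismatic
  geometry, not on real molars.
* The published absolute measurements (e.g. 249.96 mm² occlusal OES
  area) derive from scan data available only on request; they are not
  reproducible from the printed table. Applying SAET3D = SV/SAA to the
  printed occlusal inputs gives 0.715 mm, not the printed 0.751 mm —
  the thickness row evidently reflects a different post-processing
  state of the models. The implementation keeps the defining equations
  literal; only the internally consistent percentage columns are used
  as reproduction checks (and indeed one printed percentage, 59.31,
  differs by one final-digit rounding unit from its own printed inputs,
  56.80/95.78 = 59.30).
* Mesial/distal and buccal/lingual anatomical labels are conventions of
  the frame (+y is called buccal); flipping them requires user metadata.
* Multi-rooted/pulp surfaces, cusp naming, and outer (non-occlusal)
  slope measurement are out of scope.
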