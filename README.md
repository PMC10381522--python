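# enamelmap

Morphologically anchored measurement of dental enamel thickness on 3D
surface models of tooth crowns.

Micro-CT scans of teeth yield a triangulated enamel cap containing two
opposed sheets — the outer enamel surface (OES) and the enamel–dentine
junction (EDJ) — joined at the thin cervical margin. `enamelmap`
segments the two sheets, orients the tooth in its own coordinate frame
derived from the cervical edge, delineates the occlusal surface, splits
it by the mesio-distally running midline of per-section deepest points
into the inner slopes of the buccal and lingual cusps, and reports, per
sector, the **sector average enamel thickness**:

```
SAET3D = SV / SAA          SAA  = (SAedj + SAoes) / 2
SAET2D = SA / SACL         SACL = (SCLedj + SCLoes) / 2
```

where `SV` is the sector enamel volume, `SAedj`/`SAoes` the EDJ and OES
areas of the sector (in 2D: the cross-section area `SA` and contour
lengths `SCLedj`/`SCLoes` on a bucco–lingual section). Averaging both
bounding surfaces in the denominator — rather than the classical
EDJ-only convention — suits worn teeth, whose measurable enamel volume
is bounded by two irregular surfaces. For a shell of uniform thickness
*t*, both parameters converge to *t*. The package also produces
topographic thickness maps: the cloud-to-mesh distance from every OES
vertex to the EDJ, exported as a color-coded PLY.

Intended users: palaeontologists, physical anthropologists and dental
morphologists working with micro-CT-derived crown surface models
(STL/PLY/OBJ, µm or mm).

## Worked example

Real scan data is rarely redistributable, so the package ships a
synthetic-tooth generator with analytic ground truth. Build a two-cusp
molar-like crown with a uniform 0.5 mm enamel layer and run the full
pipeline:

```
$ enamelmap synth --preset two-cusp --t 0.5 --seed 1234 --out crown.ply
wrote crown.ply (+crown.truth.json): 10920 faces

$ enamelmap run --in crown.ply --out run/
run complete -> run/
occlusal SAET3D = 0.5007 mm (SV 9.79 mm3, SAA 19.54 mm2)
```

`run/report.json` holds the per-sector table (values at 6 significant
digits; identical input and configuration reproduce it byte for byte):

```json
"sectors": {
  "buccal_inner_slope":  {"SV_mm3": 4.90661, "SAoes_mm2": 9.75429,
                          "SAedj_mm2": 9.80977, "SAA_mm2": 9.78203,
                          "SAET3D_mm": 0.501594},
  "lingual_inner_slope": {"SV_mm3": 4.87873, "SAoes_mm2": 9.72864,
                          "SAedj_mm2": 9.79382, "SAA_mm2": 9.76123,
                          "SAET3D_mm": 0.499807},
  ...
}
```

Reading it: the crown was built mirror-symmetric with a 0.5 mm offset
EDJ, and the pipeline recovers SAET3D within ~0.3% of 0.5 mm on each
slope, with buccal/lingual percentage splits of 50.07/49.93 (OES area)
and 50.14/49.86 (volume) — the small asymmetries reflect mesh
discretization, not the geometry. The run directory also contains the
labeled cap (`cap_labels.ply`), the tooth frame (`frame.json`), the
occlusal contours and midline as ordered CSV polylines, the 80
bucco–lingual sections, and the topographic map (`thickness_map.ply`,
per-vertex `quality` scalar in mm plus RGB).

The same workflow is available as a library:

```python
from enamelmap import run_pipeline, PipelineConfig, make_two_cusp_crown

cap, truth = make_two_cusp_crown()
res = run_pipeline(cap, PipelineConfig(label="demo"))
print(res.report.to_json())
```

Manual corrections — the usual need on worn or pitted fossil teeth —
enter through override files (`contour_overrides`: CSV `x,y,z` points;
`midline_overrides`: CSV `section_index,y,z`; `frame_override`: frame
JSON) and a `pit_filter` flag that suppresses strongly concave
(pit-like) candidates in the deepest-point search.

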