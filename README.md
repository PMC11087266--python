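# orgzone

Zonal image analysis of organoid–immune co-cultures.

T-cell-engaging bispecific antibodies (TCBs) crosslink a tumour surface
antigen to CD3 on T cells. When the antigen (e.g. EpCAM or CEA) is also
expressed by healthy epithelium, TCBs trigger *on-target off-tumour*
toxicity. Co-cultures of patient-derived intestinal organoids (or
tumouroids) with peripheral blood mononuclear cells (PBMCs) embedded in a
solid matrix make this process measurable by microscopy: immune cells
migrate toward and into the epithelium while a caspase-3/7 reporter marks
apoptotic epithelial cells.

`orgzone` turns multi-channel fields of such co-cultures into tidy,
statistically usable tables:

- **Object detection** — a classical baseline segmenter (Otsu threshold,
  morphology, 8-connected components, hole filling) or any imported label
  mask yields filled organoid/tumouroid ROIs; only objects with area
  strictly > 7,500 µm² are kept.
- **Concentric zones** — exact Euclidean distance transforms partition each
  ROI and its surroundings with 25 µm margins into zone 1 (interior),
  zone 2 (epithelial barrier band), and zones 3–4 (proximal/distal
  extracellular space). Outward-zone pixels contested between neighbouring
  objects are deleted from all claimants.
- **Phenotyping and counting** — DAPI nuclear detection (watershed on
  distance-transform maxima), marker positivity against negative-control
  thresholds (mean + k·SD), a fixed priority order
  panCK > CD8 > CD4 > CD14 > CD20, and centroid-based zone assignment give
  per-object, per-zone, per-phenotype, per-timepoint counts.
- **Killing and integrity** — mean caspase-3/7 a.f.u. per object,
  normalized per timepoint to the non-targeting (NT) control
  (fold(c, t) = mean a.f.u.(c, t) / mean a.f.u.(NT, t)); panCK-live vs
  caspase-apoptotic pixel-class fractions of the zone-2 band.
- **Statistics** — the PBMC seeding formula
  (PBMCs = V µl × 22,000 × n), location-only ROUT outlier removal at
  Q = 2% (median centre, RSDR from the 68.27th percentile of absolute
  residuals, FDR step on t statistics), OLS R², and a deterministic report
  bundle.
- **Synthetic ground truth** — `orgzone.synthgen` generates co-culture
  fields of ring-shaped epithelial objects and immune cells with known
  positions, phenotypes, zones and apoptotic fractions, so every stage is
  validated against exact truth (the apoptotic shell fraction follows
  1 − (1 − rate)^(t/24), applied outside-in).

## Worked example

`python examples/infiltration_counts.py` generates a field of 5 organoids
and 200 immune cells, runs the full measurement pipeline, and prints:

```
timepoint  measured T cells in zones 1-2  (truth)
      0 h           0              (0)
     24 h          53              (53)
     48 h          82              (82)
     72 h         108              (108)
```

Measured counts equal the ground truth exactly: every nucleus is detected,
phenotyped and assigned to the correct concentric zone, and the rising
zone-1/2 counts quantify T-cell infiltration into the epithelium.
`python examples/killing_assay.py` prints the NT-normalized fold matrix for
four TCB-like conditions — NT is exactly 1.0 at every timepoint and folds
increase with apoptosis rate and time (EpCAM-like > CEA(hi)-like >
CEA(lo)-like). The other examples cover zone geometry vs the analytic
annulus areas, raster/ground-truth export, and the seeding/ROUT/R²
statistics.

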