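# Methods

## The measurement model

The package analyses 2-D multi-channel rasters of organoid–PBMC co-cultures
(one grayscale channel per stain; pixel size supplied in µm/px, defaults
0.50 µm/px for multiplexed immunofluorescence and 0.23 µm/px for
brightfield). The analysis chain is:

1. **Objects.** The epithelial outline (panCK + caspase composite, or any
   single channel) is thresholded, opened (1 µm) to drop noise specks,
   closed (5 µm) to bridge the shell, hole-filled, and labelled with
   8-connectivity. ROIs are *filled*: the lumen belongs to its object, which
   is what makes an interior zone well defined. Externally produced label
   masks (e.g. from a learned segmenter) can be imported instead of the
   baseline segmenter. Objects with area strictly greater than 7,500 µm²
   (pixel count × pixel size²) are retained. Touching objects are not split
   beyond connected components; merges are surfaced in the QC log.
2. **Zones.** For each object independently, exact Euclidean distance
   transforms scaled to µm define zone 2 = {ROI : d_in ≤ m},
   zone 1 = {ROI : d_in > m}, zone 3 = {background : 0 < d_out ≤ m},
   zone 4 = {background : m < d_out ≤ 2m}, with margin m = 25 µm. Zone 1 is
   the entire eroded interior (not a band), and ties at exactly one margin
   go to the band nearer the boundary, so zone1 ∪ zone2 equals the ROI
   pixel-exactly on every run. Outward-zone pixels claimed by ≥ 2 objects,
   or lying inside another ROI, are deleted from *all* claimants ("deleted",
   not "assigned to nearest"); cells on deleted pixels count in no zone.
   Results are independent of object processing order.
3. **Cells.** DAPI nuclei are thresholded and split by watershed on
   distance-transform maxima (minimum peak separation 4 µm; minimum nucleus
   area 10 µm²). Marker intensity is the mean over a 3 µm disk around the
   centroid — an approximation of membrane/cytoplasmic staining that avoids
   full cell segmentation. Positivity thresholds are mean + k·SD (default
   k = 3) of a negative-control sample (≥ 10 values). The phenotype is the
   first positive marker in the order panCK > CD8 > CD4 > CD14 > CD20, else
   "other"; panCK first guarantees epithelial cells are never miscounted as
   immune. Zone membership is decided by the single pixel under the
   centroid: deterministic and directly comparable to point-pattern truth.
4. **Killing and integrity.** Per-object killing is the *mean* caspase
   a.f.u. over the filled ROI (mean, not integrated intensity, so folds are
   object-size independent; recorded in output metadata). Folds divide each
   condition's mean by the NT-control mean of the same timepoint group (a
   plate/donor column can be added to the group key); the control's fold is
   exactly 1. Integrity is the fraction of zone-2 pixels classed
   panCK-live vs caspase-apoptotic, caspase winning double-positive pixels
   (apoptotic epithelium still expresses cytokeratin). The caspase-positive
   class threshold should come from a negative control on *untreated live
   epithelium*, not from background: live cells carry a dim reporter
   baseline that a background-derived threshold would misclassify.
5. **Statistics.** PBMC seeding uses PBMCs = V(µl) × 22,000 × n with exact
   integer arithmetic; the paired epithelial count uses the approximate
   20,000 cells/µl convention (so a 10 µl dome pairs 220,000 PBMCs with
   ~200,000 epithelial cells, E:T 1.1:1). ROUT outlier removal is
   specialized to a location-only model suited to univariate per-organoid
   distributions: centre = median, RSDR = 68.27th percentile of absolute
   residuals × n/(n−K) with K = 1 (floored at a tiny positive value so a
   majority of identical points still exposes gross outliers), and an FDR
   step that walks residuals largest-first, flagging the i-th largest while
   its two-tailed t P-value (df = n−K) is below Q·(n−i+1)/n and stopping at
   the first failure. Flagging depends only on residual magnitudes, hence is
   permutation invariant. R² comes from ordinary least squares.

## The synthetic generator

`synthgen` emulates the assay geometry at desk scale: ring-shaped epithelial
objects (organoids: 25 µm shell around a lumen; tumouroids: dense disks,
lumen radius 0) placed by rejection sampling (≤ 10,000 attempts per object,
else an error) in a 1536 × 1536 px (768 µm) field at 0.50 µm/px, default
5 objects of radius 50–70 µm with ≥ 110 µm boundary separation, and 200
immune cells (CD4 0.45 / CD8 0.35 / CD14 0.15 / CD20 0.05 — free
parameters; the assay does not fix a composition) imaged at 0/24/48/72 h.
Channels are 16-bit with background 0, signal amplitude 3000, Gaussian noise
(SD 20), and a dim caspase baseline (200) in live epithelium. One seed fixes
all randomness; identical seeds give bit-identical rasters.

Design choices a user should know:

- **Circles by construction.** Objects are annuli so zone membership has an
  analytic oracle (distance to the circle); a radial-perturbation amplitude
  produces irregular outlines for robustness experiments but voids that
  oracle.
- **Infiltration kinetics** are a Bernoulli jump model: per step of dt
  hours, each extra-epithelial cell relocates into the shell of its nearest
  object with probability rate·dt/24 (clipped to 1), landing on the ray from
  the object centre at an area-uniform radius; intra-epithelial cells are
  stationary. Collapsing "advance toward the boundary" into a single jump
  gives the infiltrated count an exact binomial closed form, which is what
  the Monte-Carlo checks verify. Expected infiltration is therefore
  monotone in rate and time.
- **Caspase accumulation**: the apoptotic fraction of each shell is
  1 − (1 − rate)^(t/24), applied outside-in (the sub-annulus [ρ, R] with
  matching area), so measured class fractions have a closed form.
- **Clearance buffers.** Cells keep ≥ 2 µm from analytic zone boundaries,
  ≥ 5 µm outside object boundaries, and ≥ 7.5 µm from each other; the
  spacing guarantees that a cell's 3 µm sampling disk can never touch a
  neighbour's 3 µm marker disk even after centroid rounding. These buffers
  make the "zero count discrepancies" recovery guarantee well posed —
  raster and analytic zone assignment can legitimately differ within ~1 px
  of a boundary, and the zones oracle test allows exactly that.
- **Simplifications** relative to real data: a single 2-D plane stands in
  for ~450 µm z-stacks / projections; DAPI renders immune nuclei only
  (epithelial nuclei omitted, so nuclear detection isolates the immune
  compartment and epithelium is identified via cytokeratin);
  intra-epithelial cells carve a 4 µm hole in the epithelial channels
  (lymphocyte intercalation displacing cytokeratin locally); no TCR
  signalling, cytokine fields, or pharmacology. Passing tests therefore
  demonstrate correctness of the *measurement* chain under controlled
  geometry and noise — not segmentation robustness on real texture, nor
  biological kinetics.

## Numerical choices and degenerate inputs

- Thresholding guard: Otsu splits pure noise and keeps ~25% of pixels, so
  images where Otsu retains > 20% foreground are treated as signal-free
  (stained objects in these assays cover far less of the field).
- EDT distances are centre-to-centre, so measured band edges sit within one
  pixel of the analytic circle; zone areas of a radius-100 µm disk agree
  with the annulus formulas to < 0.4% at 0.5 µm/px.
- ROIs thinner than the margin have an empty zone 1 (valid, logged); blank
  rasters segment to empty masks with a warning; a disconnected label is
  split and relabelled.
- Problem sizes in tests and examples (fields of 768–2048 px, 2–12 objects,
  20 seeds for the recovery sweep, 200 Monte-Carlo replicates for ROUT)
  were chosen as the smallest sizes at which the statistical checks have
  comfortable power.

## Known limitations

- No watershed splitting of touching objects; nearby objects may merge
  under the 5 µm closing and are only flagged, not separated.
- Nuclei closer than the minimum peak separation merge into one detection.
- Marker positivity is binary; no per-cell intensity quantification beyond
  the 3 µm-disk mean, and no cell tracking across timepoints (the assay
  images sacrificial fixed samples).
- The fold normalization assumes a positive-mean NT control in every
  timepoint group and fails loudly otherwise.
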