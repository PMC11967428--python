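# Methods

This note documents the models and procedures behind `trogoquant`, the
parameters that matter, what the synthetic generator does and does not
emulate, and the design choices made where the design was genuinely open.

## The measurement model

The package quantifies a trogocytic marker (a leukocyte protein such as
CD45RA) on tumor cells in 2D multichannel fluorescence images. The central
difficulty is that no membrane stain delineates individual tumor cells, so
"per cell" must be defined constructively:

* Tumor **tissue** is whatever the epithelial marker (pan-cytokeratin)
  stains above threshold.
* A tumor **cell** is the Voronoi territory of one tumor nucleus inside
  that tissue: every tumor-tissue pixel belongs to the nucleus whose
  instance is nearest in Euclidean distance. This generalized (region-seed)
  Voronoi diagram reduces to the familiar point diagram for point seeds and
  is robust to nucleus size and shape.
* A cell's **surface area** — the denominator of the coverage fraction — is
  its territory area. This is the single strongest modeling assumption in
  the pipeline and is stated prominently because the trogocytic flag is a
  ratio to it.

Coverage is a ratio of integer pixel counts, computed once, so it is exact
given the masks. The trogocytic flag is strict on both ends:
`0.55 < coverage < 0.90`. The window is deliberately conservative — the
lower bound excludes incidental or punctate staining, the upper bound
excludes cells whose apparent signal is autofluorescence or a bright
artifact (paraffin debris saturates whole territories).

## Segmentation

The default nucleus detector is classical and deterministic: Gaussian
smoothing (σ 0.6 µm) → Otsu → hole filling → Euclidean distance transform →
watershed seeded at distance maxima at least 3 µm apart, 4-connected
instances, ridge lines to background, labels canonicalized by first-pixel
raster order so repeated runs compare bit-exact. Learned segmenters
typically outperform classical ones on crowded tissue; rather than bundling
trained weights, the pipeline accepts any external label raster
(`read_label_image`), which is also how the validation suite injects
ground-truth nuclei so that segmentation error does not contaminate
downstream checks. The area filter (6–250 µm²) rejects debris and fused
clumps; both bounds are configuration.

## Voronoi territories

Distances are computed in the full plane and then masked (matching the
common raster-tool behavior), not geodesically within the mask; geodesic
tessellation is out of scope. Ties are broken toward the lower nucleus id.
Implementation: one exact Euclidean distance transform per instance,
compared as exact integer squared distances, so the tie rule is
bit-reproducible. The suite checks exact agreement with a brute-force
per-pixel nearest-instance search on hundreds of random fixtures, and the
partition property (territory areas sum to the mask area) on every field.
"Encapsulated by the tumor border" is read as a nucleus having ≥ 50% of its
pixels inside the tumor mask (configurable); the threshold choice only
affects nuclei straddling the tissue boundary.

## Marker conditioning and the two intensity scales

Processing order is fixed: background subtraction → CLAHE → binarization.

* **Background subtraction** is morphological opening with a disk (default
  radius 10 µm ≈ 50 px at 0.2 µm/px, the radius conventional in
  rolling-ball tools), subtracted and clipped at zero. Opening is exact on
  linear shading (a ramp is invariant under opening, so it is removed
  entirely) and preserves features smaller than the disk.
* **CLAHE** (tile 64 px, clip limit 0.01, 256 bins) equalizes local
  contrast ahead of binarization. It is a *per-image, per-tile* transform:
  two images' CLAHE outputs are not on a common scale. Consequently all
  quantitative per-cell intensities — and the control gate derived from
  them — are measured on the *linear* background-subtracted channel;
  CLAHE output feeds only the coverage mask. Collapsing these two scales
  is a real failure mode (a gate learned on equalized controls never fires
  on equalized samples) and the split is deliberate.
* **Binarization** is Otsu by default; a fixed threshold and a
  control-gate threshold (applied on the linear channel) are selectable
  because the published procedure does not fix which binary the coverage
  rule consumed.

The expression gate is the imaging analog of an isotype/FMO gate: the 99th
percentile (linear-interpolation definition) of per-cell mean intensities
pooled from secondary-antibody-only control fields, requiring ≥ 10 control
cells. By construction the gate marks 1% of its control population; on
independent control cells the false-positive rate is 1% in expectation with
a spread that combines binomial noise and the gate's quantile-estimation
error (~0.3 pp each at 1,000 + 1,000 cells) — the validation suite asserts
the exact in-sample calibration and a 3σ band on the hold-out rate.

## Trogosome morphometry

Trogosomes appear in a single plane as bright disks or, mostly, hollow
rings. Scale-space blob detection applied directly to a ring locks onto the
annulus thickness, not the sphere diameter (≈ −75% diameter error for
rings ≥ 5 µm in our experiments), so detection runs on a grayscale
hole-filled image: morphological reconstruction by erosion (4-connected, so
one-pixel diagonal joints still seal the annulus) turns rings into plateaus
and leaves disks untouched. On the filled image the scale-normalized
Laplacian-of-Gaussian is maximized near the center at σ ≈ r/√2. Diameter is
then refined as twice the radius at which the azimuthally averaged radial
profile falls to half the plateau level — the equivalent-circle diameter,
accurate to a few percent across 2–10 µm; the raw 2√2σ estimate remains as
a fallback when the profile has no crossing. Detections are merged when
centers are closer than half the smaller diameter or when most of the
smaller circle lies inside the larger (ring-edge responses of a large
sphere otherwise survive as small off-center blobs). A detection must lie
inside a territory and outside its owner's nucleus — trogosomes sit beside
and deform the nucleus rather than within it. Hollowness is the mean
intensity of the central disk (0.4 r) over the 0.7–1.0 r annulus; values
below 1 indicate a hollow shell; radii under 2 px are flagged degenerate.
The large-trogosome call is strictly `diameter > 5 µm` (configurable), and
a cell counts once per timepoint however many large trogosomes it holds.

## The synthetic generator

The generator produces the two field types the pipeline consumes, with
exact ground truth.

**FFPE fields** (defaults: 128×128 µm at 0.2 µm/px, 100 tumor cells inside
a wobbly-disk tumor region, 20 stromal cells outside, nuclei 2.5 ± 0.3 µm
radius clipped at ±3 sd, ≥ 6 µm spacing by dart-throwing): ground-truth
territories are computed with the pipeline's own region-Voronoi operator on
the planted nucleus disks, so planted and measurable geometry coincide; the
marker channel receives, per cell, an exact `round(c·N)`-pixel random
subset of its territory (the achieved fraction is recorded), rendered
without PSF so pre-noise coverage is an exact pixel ratio. 40% of cells
express the marker with coverage ~ U(0.3, 0.95) by default; non-expressing
cells carry none.

**Co-culture fields** (defaults: 240×240 µm at 0.25 µm/px, 100 cells with
4 µm nuclei at ≥ 20 µm spacing on a jittered grid, as a confluent
monolayer): selected cells receive one trogosome ring — annulus at full
amplitude from 0.7 r to r (at least 2 px thick so rasterization stays
watertight), interior at 30% of ring intensity — placed to fit inside the
territory with its center off the nucleus. Exactly `round(f·n)` cells get a
large-range diameter (U(5.5, 9) µm), 30% of the rest a small one
(U(1.8, 4.5) µm); the default timecourse plants large-trogosome prevalences
of 10 / 35 / 62% at 4 / 8 / 16 h, rising with contact time as trogosome
accumulation does.

**Nuisance models**, independently switchable so each robustness property
isolates one effect: Gaussian PSF of σ 0.4 px (the diffraction-limited
width of high-NA 60× imaging at this sampling; applied to nuclei, tumor and
ring channels), per-cell lognormal autofluorescence (median 0.02, σ_log
0.35, plus a 0.01 base — the entire content of a secondary-antibody-only
control), scaled-Poisson shot noise (scale 300), Gaussian read noise
(σ 0.01) and a linear shading ramp (amplitude 0.05). `noiseless()` switches
all of them off. Everything derives from one seeded generator; identical
parameters and seed give bit-identical fields.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: irregular (non-convex, lobed) nuclei and the
corresponding StarDist-class segmentation difficulty, spatially clumped
rather than uniform marker puncta, true membrane boundaries deviating from
Voronoi geometry, out-of-focus light and 3D structure, spectral bleed-
through, and section/batch effects across a cohort. Recovery results on
synthetic fields bound algorithmic error, not biological model error.

## Validation conditions and problem sizes

The validation suite (`trogoquant.validation`, exercised by
`tests/test_acceptance.py` and `scripts/acceptance.py`) fixes these
conditions: 200 random ≤ 64×64 fixtures for the brute-force tessellation
oracle; one noiseless 100-cell FFPE field with coverages spanning [0, 1]
(plus one planted at exactly 30% flaggable) for coverage/flag recovery,
measured through the pipeline with ground-truth nuclei labels; 40 + 40
25-cell control fields (1,000 gate + 1,000 hold-out cells) for gate
calibration; a 2–10 µm diameter grid in a 36-cell field plus three
100-cell timecourse fields for trogosome morphometry; and 50 randomized
trials per monotonicity property. These sizes keep the full run at a few
minutes on one CPU while leaving every recovery margin comfortably wide of
its tolerance.

## Numerical choices and degenerate inputs

Thresholding uses `>=` on the resolved threshold (Otsu's returned value is
nudged one ulp up to match the conventional strict-greater upper class).
Flat channels yield empty results with warnings, not errors: an empty field
of view is a valid observation. Percentiles use NumPy's linear
interpolation. Label maps are always relabeled to consecutive ids in
first-pixel raster order; all determinism guarantees are stated at the
byte level. Border-touching cells are retained but flagged
(`touches_border`) since territory truncation biases coverage; exclusion is
a config switch. Zero-cell fields, empty record sets and zero-cell
timepoints produce flagged null summaries.

## Known limitations

Single 2D planes only (no Z-stacks or 3D reconstruction); no proprietary
microscope formats (convert to TIFF); no flat-field correction from
calibration images or spectral unmixing; the classical nucleus detector
under-splits heavily overlapping nuclei compared to learned models (use the
external-labels path); Voronoi territories mis-assign pixels wherever true
cell boundaries deviate strongly from nearest-nucleus geometry; and the
trogosome detector assumes approximately circular cross-sections — strongly
deformed or clustered trogosomes merge or split.
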