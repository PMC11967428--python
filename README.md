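# trogoquant

Per-cell quantification of trogocytosed immune-cell marker on tumor cells in
multichannel fluorescence images.

Trogocytosis — the nibbling of membrane fragments and proteins from a donor
cell by an acceptor cell — lets tumor cells acquire and display leukocyte
proteins such as CD45/CD45RA. In stained tissue this shows up as a
leukocyte-marker signal *on tumor cells*, and in co-cultures as intracellular
marker-coated spheres ("trogosomes"). `trogoquant` turns such multichannel
images (nuclei / pan-cytokeratin / trogocytic marker) into per-cell tables:
which tumor cells carry the marker, what fraction of each cell it covers, and
which cells contain trogosomes of what diameter. It is written for imaging
groups quantifying tumor–immune protein transfer in FFPE cohorts and
co-culture experiments.

## Method

For a field with channels $(I_{\mathrm{nuc}}, I_{\mathrm{PanCk}},
I_{\mathrm{marker}})$ and pixel size $s$ (µm/px):

1. **Nuclei** — instance segmentation of $I_{\mathrm{nuc}}$ (Gaussian
   smoothing → Otsu → hole filling → distance transform → peak-seeded
   watershed), or an external label image from any segmenter; instances
   outside a physiological area window are discarded as debris.
2. **Tumor mask** — threshold $I_{\mathrm{PanCk}}$ (Otsu or fixed), fill
   small holes. Nuclei with ≥ 50% of their pixels inside the mask are tumor
   nuclei.
3. **Cell territories** — each tumor-mask pixel is assigned to the nearest
   tumor nucleus (Euclidean distance to the nearest pixel of each instance;
   ties to the lower id): a nuclei-seeded Voronoi tessellation restricted to
   tumor tissue, the 2D proxy for cell extent when no membrane stain exists.
4. **Marker conditioning** — rolling-ball style background subtraction
   (morphological opening with a disk, default radius 10 µm), then CLAHE for
   the binarization path only; per-cell mean intensities stay in linear
   units so they are comparable across images.
5. **Scoring** — per cell $k$ the coverage fraction
   $c_k = |M \cap T_k| / |T_k|$ (marker-positive pixels in the territory
   over territory pixels). A cell is **trogocytic** iff $0.55 < c_k < 0.90$
   — both bounds strict; the upper bound discards autofluorescent cells and
   bright anomalies such as paraffin debris. A cell **expresses** the marker
   iff its linear mean intensity exceeds the 99th percentile of per-cell
   means from secondary-antibody-only control fields.
6. **Trogosomes** (co-culture) — grayscale hole filling by morphological
   reconstruction (hollow rings become solid plateaus), multiscale
   Laplacian-of-Gaussian detection over a 1.5–12 µm diameter range,
   overlap-based merging, diameter from the half-max radius of the radial
   intensity profile, and a hollowness index (central / annulus mean
   intensity). A trogosome is **large** iff its diameter strictly exceeds
   5 µm; per timepoint the package reports the percentage of cells
   containing at least one.

A synthetic-field generator plants all of these quantities with exact ground
truth (per-cell coverage as exact pixel-count subsets, trogosome rings of
known diameter and hollowness, switchable noise models), so every stage is
testable without external data.

## Worked example

`examples/trogosome_timecourse.py` simulates a 4 h / 8 h / 16 h co-culture
(100 cells per timepoint, camera noise enabled) and runs detection:

```
4h: 44 trogosomes in 100 cells; 10% of cells hold one >5 µm (planted 10%)
     diameter 3.9 ± 2.2 µm, median hollowness 0.36 (<1 means hollow)
8h: 55 trogosomes in 100 cells; 35% of cells hold one >5 µm (planted 35%)
     diameter 5.9 ± 2.4 µm, median hollowness 0.35 (<1 means hollow)
16h: 74 trogosomes in 100 cells; 62% of cells hold one >5 µm (planted 62%)
     diameter 6.6 ± 2.0 µm, median hollowness 0.35 (<1 means hollow)
```

The percentage of cells holding a large trogosome is the timecourse readout
and matches the planted fractions exactly; hollowness well below 1 confirms
the detected spheres are marker-coated shells rather than filled vesicles.
`examples/quantify_ffpe_field.py` (per-cell coverage and the strict 55–90%
flag on an FFPE-like field) and `examples/expression_gate_from_controls.py`
(expression gating against secondary-only controls) print the corresponding
FFPE readouts.

## Command line

```
trogoquant quantify sample1.tif --pixel-size-um 0.11 \
    --channels nuclei=0,tumor=1,marker=2 \
    --control ctrl1.tif --control ctrl2.tif --out results/
trogoquant trogosomes t4.tif t8.tif t16.tif --timepoints 4h,8h,16h \
    --pixel-size-um 0.11 --out results/
trogoquant simulate --kind ffpe --seed 1 --out fixtures/
```

Each run writes CSV tables (cells, samples, trogosomes, timepoints), audit
label images, and a manifest (config snapshot, input hashes, version, seed)
sufficient to reproduce the outputs.

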