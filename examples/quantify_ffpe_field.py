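"""Quantify trogocytosed-marker coverage per tumor cell in an FFPE-like field.

Generates a synthetic tumor field with known per-cell marker coverage, runs
the full quantification chain (nucleus detection → tumor mask → Voronoi
territories → marker conditioning → coverage scoring), and compares the
result to the planted ground truth.
"""

import numpy as np

from trogoquant import (
    PipelineConfig,
    SyntheticParams,
    generate_ffpe_field,
    quantify_image,
    summarize_sample,
)

# a 128x128 µm field with 100 tumor cells; 40% of them carry marker coverage
# drawn from U(0.3, 0.95), with shot noise, read noise and shading enabled
params = SyntheticParams(seed=0)
image, truth = generate_ffpe_field(params)

result = quantify_image(image, PipelineConfig(), group="stage II")
sample = result.sample

print(f"field {image.source_id}: {sample.n_tumor_cells} tumor cells")
print(f"  trogocytic (coverage strictly within 55-90%): "
      f"{sample.n_trogocytic} cells = {sample.pct_trogocytic:.1f}%")

planted_flaggable = (
    (truth.planted_coverage > 0.55) & (truth.planted_coverage < 0.90)
).mean() * 100
print(f"  planted flaggable fraction: {planted_flaggable:.1f}%")

coverages = np.array([r.coverage_fraction for r in result.records])
print(f"  measured coverage: median {np.median(coverages):.2f}, "
      f"range {coverages.min():.2f}-{coverages.max():.2f}")
print("The trogocytic percentage is the field-level readout; the strict "
      "55/90 bounds exclude unstained cells and bright artifacts.")
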