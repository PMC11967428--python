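"""End-to-end orchestration: image → tables, with reproducible manifests.

``quantify_image`` runs the full FFPE quantification chain (nucleus
detection or external labels → tumor mask → Voronoi territories → marker
conditioning → per-cell coverage and flags); ``trogosome_image`` runs the
co-culture chain (territories → trogosome detection → timepoint summary).
Both are deterministic given image + config, which is what the run manifest
records.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .errors import ValidationError
from .image_io import MultiChannelImage, PipelineConfig
from .marker_processing import (
    ControlGate,
    binarize_marker,
    clahe_normalize,
    control_threshold,
    subtract_background,
)
from .scoring import CellRecord, SampleResult, score_cells, summarize_sample
from .segmentation import NucleiLabels, detect_nuclei, filter_nuclei
from .trogosome import TimepointSummary, detect_trogosomes, summarize_timepoint
from .tumor_map import CellMap, binarize_tumor_marker, select_tumor_nuclei, voronoi_territories

__all__ = [
    "PipelineResult",
    "RunManifest",
    "segment_image",
    "build_cell_map",
    "process_marker_channel",
    "quantify_image",
    "control_gate_from_images",
    "trogosome_image",
]


@dataclass
class PipelineResult:
    """Everything one quantification run produced, for tables and audit."""

    records: list[CellRecord]
    sample: SampleResult
    nuclei: NucleiLabels
    cells: CellMap
    marker_mask: np.ndarray
    linear_marker: np.ndarray
    normalized_marker: np.ndarray


def segment_image(
    image: MultiChannelImage,
    config: PipelineConfig,
    nuclei_labels: NucleiLabels | None = None,
) -> NucleiLabels:
    """Nucleus instances: external labels if given, else the built-in detector."""
    if nuclei_labels is None:
        nuclei_labels = detect_nuclei(
            image.channel("nuclei"),
            image.pixel_size_um,
            smoothing_sigma_um=config.seg_smoothing_sigma_um,
            peak_min_distance_um=config.seg_peak_min_distance_um,
        )
    return filter_nuclei(
        nuclei_labels,
        config.seg_min_area_um2,
        config.seg_max_area_um2,
        image.pixel_size_um,
    )


def build_cell_map(
    image: MultiChannelImage,
    config: PipelineConfig,
    nuclei: NucleiLabels,
) -> tuple[NucleiLabels, CellMap]:
    """Tumor mask → tumor-nucleus selection → Voronoi territories."""
    tumor = binarize_tumor_marker(
        image.channel("tumor_marker"),
        method=config.tumor_threshold_method,
        threshold=config.tumor_threshold_value,
        smoothing_sigma_um=config.tumor_smoothing_sigma_um,
        min_hole_um2=config.tumor_min_hole_um2,
        pixel_size_um=image.pixel_size_um,
    )
    tumor_nuclei = select_tumor_nuclei(nuclei, tumor, config.nucleus_overlap_fraction)
    cells = voronoi_territories(tumor_nuclei, tumor, image.pixel_size_um)
    return tumor_nuclei, cells


def process_marker_channel(
    image: MultiChannelImage, config: PipelineConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Condition the marker channel; returns ``(linear, normalized)``.

    ``linear`` is the background-subtracted channel in the camera's intensity
    units — the basis for per-cell mean intensities and the control gate,
    which must be comparable *across* images.  ``normalized`` additionally
    applies CLAHE, a per-image contrast stretch that helps binarization but
    destroys cross-image comparability; it feeds the coverage mask only.
    """
    channel = np.asarray(image.channel("trogo_marker"), dtype=np.float64)
    if config.background_subtraction:
        channel = subtract_background(
            channel, config.background_radius_um, image.pixel_size_um
        )
    normalized = channel
    if config.clahe:
        normalized = clahe_normalize(
            channel, tile_px=config.clahe_tile_px, clip_limit=config.clahe_clip_limit
        )
    return channel, normalized


def quantify_image(
    image: MultiChannelImage,
    config: PipelineConfig | None = None,
    nuclei_labels: NucleiLabels | None = None,
    gate: ControlGate | None = None,
    group: str = "",
) -> PipelineResult:
    """Full per-cell quantification of one FFPE field."""
    config = config or PipelineConfig()
    for role in ("nuclei", "tumor_marker", "trogo_marker"):
        if not image.has_role(role):
            raise ValidationError(f"image {image.source_id!r} lacks the {role!r} channel")
    nuclei = segment_image(image, config, nuclei_labels)
    tumor_nuclei, cells = build_cell_map(image, config, nuclei)
    linear, normalized = process_marker_channel(image, config)
    if config.marker_threshold_method == "control_gate":
        # the gate lives in linear units; CLAHE output is not comparable
        marker = binarize_marker(linear, "control_gate", gate=gate)
    else:
        marker = binarize_marker(
            normalized,
            method=config.marker_threshold_method,
            threshold=config.marker_threshold_value,
        )
    records = score_cells(
        cells,
        tumor_nuclei,
        marker,
        linear,
        source_id=image.source_id,
        gate=gate,
        low=config.coverage_low,
        high=config.coverage_high,
        exclude_border_cells=config.exclude_border_cells,
    )
    sample = summarize_sample(records, group=group)
    return PipelineResult(records, sample, tumor_nuclei, cells, marker.mask, linear, normalized)


def control_gate_from_images(
    control_images: Sequence[MultiChannelImage],
    config: PipelineConfig | None = None,
    nuclei_labels: Sequence[NucleiLabels] | None = None,
) -> ControlGate:
    """Expression gate from secondary-antibody-only control fields.

    Each control field is segmented and tessellated like a sample; the
    per-cell mean processed-marker intensities are pooled and the configured
    percentile becomes the gate threshold.
    """
    from scipy import ndimage as ndi

    config = config or PipelineConfig()
    intensities: list[float] = []
    for i, image in enumerate(control_images):
        ext = nuclei_labels[i] if nuclei_labels is not None else None
        nuclei = segment_image(image, config, ext)
        tumor_nuclei, cells = build_cell_map(image, config, nuclei)
        if cells.count == 0:
            continue
        linear, _ = process_marker_channel(image, config)
        means = ndi.mean(linear, cells.territories, cells.territory_ids())
        intensities.extend(np.atleast_1d(means).tolist())
    return control_threshold(intensities, config.control_percentile)


def trogosome_image(
    image: MultiChannelImage,
    config: PipelineConfig | None = None,
    timepoint: str = "",
    nuclei_labels: NucleiLabels | None = None,
) -> tuple[list, TimepointSummary, CellMap]:
    """Co-culture chain: territories, trogosome detection, timepoint summary.

    Detection runs on the background-subtracted marker channel in linear
    intensities (CLAHE is a binarization aid for coverage scoring, not a
    precondition for scale-space detection).
    """
    config = config or PipelineConfig()
    nuclei = segment_image(image, config, nuclei_labels)
    tumor_nuclei, cells = build_cell_map(image, config, nuclei)
    channel = np.asarray(image.channel("trogo_marker"), dtype=np.float64)
    if config.background_subtraction:
        channel = subtract_background(
            channel, config.background_radius_um, image.pixel_size_um
        )
    records = detect_trogosomes(
        channel,
        cells,
        tumor_nuclei,
        diameter_range_um=(config.trog_min_diameter_um, config.trog_max_diameter_um),
        pixel_size_um=image.pixel_size_um,
        response_threshold=config.trog_response_threshold,
        large_cutoff_um=config.trog_large_cutoff_um,
        source_id=image.source_id,
    )
    summary = summarize_timepoint(records, cells, timepoint, config.trog_large_cutoff_um)
    return records, summary, cells


@dataclass
class RunManifest:
    """Reproducibility record: config snapshot, input hashes, version, seed."""

    config: dict
    inputs: dict
    package_version: str
    seed: int
    created_utc: str

    @classmethod
    def create(
        cls, config: PipelineConfig, input_paths: Sequence[str | Path], seed: int
    ) -> "RunManifest":
        hashes = {}
        for p in input_paths:
            p = Path(p)
            digest = hashlib.sha256(p.read_bytes()).hexdigest() if p.exists() else None
            hashes[str(p)] = digest
        return cls(
            config=config.to_dict(),
            inputs=hashes,
            package_version=__version__,
            seed=seed,
            created_utc=datetime.now(timezone.utc).isoformat(),
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")
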