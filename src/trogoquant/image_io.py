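"""Reading and writing of images, label rasters, config and result tables.

Coordinate convention, used everywhere in the package: rasters are row-major
with 0-based indices; ``(x, y)`` in output tables means ``(column, row)``.
Areas are reported in µm² and diameters in µm, converted through
``pixel_size_um``; pixel-level intermediates stay in pixels.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import ValidationError
from .segmentation import NucleiLabels, canonical_relabel

__all__ = [
    "MultiChannelImage",
    "PipelineConfig",
    "read_multichannel",
    "read_label_image",
    "write_label_image",
    "write_cell_table",
    "write_trogosome_table",
    "write_sample_table",
]

logger = logging.getLogger(__name__)

ROLES = ("nuclei", "tumor_marker", "trogo_marker")

CELL_TABLE_COLUMNS = [
    "source_id",
    "cell_id",
    "centroid_x_px",
    "centroid_y_px",
    "territory_area_um2",
    "mean_marker_intensity",
    "coverage_fraction",
    "expresses_marker",
    "is_trogocytic",
    "touches_border",
]

TROGOSOME_TABLE_COLUMNS = [
    "source_id",
    "cell_id",
    "trogosome_id",
    "centroid_x_px",
    "centroid_y_px",
    "diameter_um",
    "is_large",
    "hollowness",
]

SAMPLE_TABLE_COLUMNS = [
    "source_id",
    "group",
    "n_tumor_cells",
    "n_expressing",
    "pct_expressing",
    "n_trogocytic",
    "pct_trogocytic",
]


@dataclass(frozen=True)
class MultiChannelImage:
    """A 2D multichannel fluorescence field with named channel roles.

    ``pixels`` has shape ``(n_channels, height, width)``.  ``channel_roles``
    maps role names (``nuclei``, ``tumor_marker``, ``trogo_marker``) to
    channel indices.  ``pixel_size_um`` is the physical size of one pixel.
    """

    pixels: np.ndarray
    channel_roles: Mapping[str, int]
    pixel_size_um: float
    source_id: str = "image"

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim == 2:
            px = px[np.newaxis]
        if px.ndim != 3 or px.size == 0:
            raise ValidationError("pixels must be a nonempty (C, H, W) array")
        object.__setattr__(self, "pixels", px)
        if self.pixel_size_um is None or not self.pixel_size_um > 0:
            raise ValidationError("pixel_size_um must be > 0")
        for role, idx in self.channel_roles.items():
            if role not in ROLES:
                raise ValidationError(f"unknown channel role {role!r}; valid: {ROLES}")
            if not (0 <= int(idx) < px.shape[0]):
                raise ValidationError(
                    f"role {role!r} references channel {idx}, "
                    f"but the image has {px.shape[0]} channel(s)"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[1:]

    def channel(self, role: str) -> np.ndarray:
        if role not in self.channel_roles:
            raise ValidationError(f"image {self.source_id!r} has no {role!r} channel")
        return self.pixels[self.channel_roles[role]]

    def has_role(self, role: str) -> bool:
        return role in self.channel_roles


@dataclass
class PipelineConfig:
    """All tunable parameters of the quantification pipeline.

    Physical parameters carry µm units and are converted per image through its
    pixel size; the coverage bounds and the large-trogosome cutoff are the
    published flagging constants and default to 0.55/0.90 and 5 µm.
    """

    # nucleus segmentation
    seg_smoothing_sigma_um: float = 0.6
    seg_peak_min_distance_um: float = 3.0
    seg_min_area_um2: float = 6.0
    seg_max_area_um2: float = 250.0
    # tumor mask
    tumor_threshold_method: str = "otsu"  # "otsu" | "fixed"
    tumor_threshold_value: float | None = None
    tumor_smoothing_sigma_um: float = 0.3
    tumor_min_hole_um2: float = 30.0
    nucleus_overlap_fraction: float = 0.5
    # marker processing
    background_subtraction: bool = True
    background_radius_um: float = 10.0
    clahe: bool = True
    clahe_tile_px: int = 64
    clahe_clip_limit: float = 0.01
    marker_threshold_method: str = "otsu"  # "otsu" | "fixed" | "control_gate"
    marker_threshold_value: float | None = None
    control_percentile: float = 99.0
    # trogocytosis coverage flag
    coverage_low: float = 0.55
    coverage_high: float = 0.90
    exclude_border_cells: bool = False
    # trogosome morphometry
    trog_min_diameter_um: float = 1.5
    trog_max_diameter_um: float = 12.0
    trog_large_cutoff_um: float = 5.0
    trog_response_threshold: float = 0.08
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.coverage_low < self.coverage_high <= 1):
            raise ValidationError("need 0 <= coverage_low < coverage_high <= 1")
        if not (0 < self.trog_min_diameter_um < self.trog_max_diameter_um):
            raise ValidationError("trogosome diameter range must be positive and ordered")
        if not (
            self.trog_min_diameter_um
            <= self.trog_large_cutoff_um
            <= self.trog_max_diameter_um
        ):
            raise ValidationError("large-trogosome cutoff must lie in the search range")
        if not (0 <= self.nucleus_overlap_fraction <= 1):
            raise ValidationError("nucleus_overlap_fraction must be in [0, 1]")
        if not (0 < self.control_percentile < 100):
            raise ValidationError("control_percentile must be in (0, 100)")
        if self.tumor_threshold_method not in ("otsu", "fixed"):
            raise ValidationError("tumor_threshold_method must be 'otsu' or 'fixed'")
        if self.marker_threshold_method not in ("otsu", "fixed", "control_gate"):
            raise ValidationError(
                "marker_threshold_method must be 'otsu', 'fixed' or 'control_gate'"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)


def _pixel_size_from_tiff(tif: tifffile.TiffFile) -> float | None:
    """Best-effort pixel size (µm) from OME metadata or resolution tags."""
    try:
        if tif.ome_metadata:
            import re

            m = re.search(r'PhysicalSizeX="([0-9.eE+-]+)"', tif.ome_metadata)
            if m:
                return float(m.group(1))
    except Exception:  # pragma: no cover - malformed metadata
        pass
    try:
        page = tif.pages[0]
        tag = page.tags.get("XResolution")
        unit = page.tags.get("ResolutionUnit")
        if tag is not None and unit is not None:
            num, den = tag.value
            if num and den:
                per_unit = num / den
                scale = {2: 25400.0, 3: 10000.0}.get(int(unit.value))  # inch, cm → µm
                if scale and per_unit > 0:
                    return scale / per_unit
    except Exception:  # pragma: no cover
        pass
    return None


def read_multichannel(
    path: str | Path,
    channel_roles: Mapping[str, int],
    pixel_size_um: float | None = None,
    source_id: str | None = None,
) -> MultiChannelImage:
    """Read a single- or multi-page grayscale TIFF as a MultiChannelImage.

    Intensities are preserved bit-exact.  If the file carries pixel-size
    metadata *and* ``pixel_size_um`` is supplied, the supplied value wins and
    a warning is logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta_px = _pixel_size_from_tiff(tif)
    if data.ndim == 2:
        data = data[np.newaxis]
    if data.ndim != 3:
        raise ValidationError(f"{path}: expected 2D page(s), got shape {data.shape}")
    if meta_px is not None and pixel_size_um is not None:
        if not np.isclose(meta_px, pixel_size_um, rtol=1e-3):
            logger.warning(
                "%s: file metadata pixel size %.6g µm differs from supplied %.6g µm; "
                "using the supplied value",
                path,
                meta_px,
                pixel_size_um,
            )
    effective = pixel_size_um if pixel_size_um is not None else meta_px
    if effective is None:
        raise ValidationError(f"{path}: no pixel size in metadata and none supplied")
    return MultiChannelImage(
        pixels=data,
        channel_roles=dict(channel_roles),
        pixel_size_um=float(effective),
        source_id=source_id or path.stem,
    )


def read_label_image(path: str | Path) -> NucleiLabels:
    """Read an integer label raster (e.g. from an external instance segmenter).

    Values are relabeled to consecutive positive integers; 0 stays background.
    The partition is preserved exactly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = tifffile.imread(path)
    if data.ndim != 2:
        raise ValidationError(f"{path}: label image must be 2D, got {data.shape}")
    if np.issubdtype(data.dtype, np.floating):
        if not np.all(np.mod(data, 1) == 0):
            raise ValidationError(f"{path}: label image has non-integer values")
        data = data.astype(np.int64)
    if not np.issubdtype(data.dtype, np.integer):
        raise ValidationError(f"{path}: label image must be integer-valued")
    if data.size and data.min() < 0:
        raise ValidationError(f"{path}: label image has negative values")
    return NucleiLabels(canonical_relabel(data.astype(np.int64)))


def write_label_image(labels: np.ndarray, path: str | Path) -> None:
    """Write an integer label raster as a TIFF (lossless round trip)."""
    arr = np.asarray(labels)
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValidationError("label raster must be integer-valued")
    tifffile.imwrite(os.fspath(path), arr.astype(np.int32), photometric="minisblack")


def _write_table(df: pd.DataFrame, columns: list[str], path: str | Path) -> None:
    for col in columns:
        if col not in df.columns:
            df[col] = pd.Series(dtype=object)
    df.to_csv(path, index=False, columns=columns)


def write_cell_table(records, path: str | Path) -> None:
    """Write per-cell records as CSV (one row per tumor cell).

    Floats are serialized at full precision, so a write → read round trip
    reproduces coverage fractions to better than 1e-12.
    """
    from .scoring import cell_records_to_frame

    _write_table(cell_records_to_frame(records), CELL_TABLE_COLUMNS, path)


def write_trogosome_table(records, path: str | Path) -> None:
    """Write per-trogosome records as CSV."""
    from .trogosome import trogosome_records_to_frame

    _write_table(trogosome_records_to_frame(records), TROGOSOME_TABLE_COLUMNS, path)


def write_sample_table(samples, path: str | Path) -> None:
    """Write per-sample summaries as CSV."""
    from .scoring import sample_results_to_frame

    _write_table(sample_results_to_frame(samples), SAMPLE_TABLE_COLUMNS, path)
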