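"""Tumor-tissue masking and nuclei-seeded Voronoi cell territories.

The tumor mask comes from thresholding the epithelial marker channel
(pan-cytokeratin).  Each retained nucleus then claims the tumor-mask pixels
nearer to it than to any other nucleus — a generalized (region-seeded) Voronoi
tessellation that serves as the 2D stand-in for cell extent when no membrane
stain exists.  Distances are Euclidean, computed in the full plane and then
masked; ties go to the lower nucleus id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_holes

from .errors import ValidationError
from .segmentation import NucleiLabels, canonical_relabel

__all__ = ["TumorMask", "CellMap", "binarize_tumor_marker", "select_tumor_nuclei", "voronoi_territories"]


@dataclass(frozen=True)
class TumorMask:
    """Boolean tumor-tissue mask with the threshold that produced it."""

    mask: np.ndarray
    threshold_used: float
    area_px: int = field(init=False)

    def __post_init__(self):
        mask = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "area_px", int(mask.sum()))


@dataclass(frozen=True)
class CellMap:
    """Per-nucleus Voronoi territories restricted to the tumor mask.

    ``territories`` is an integer raster: 0 outside tumor tissue, ``k > 0``
    for the territory of tumor nucleus ``k`` (territory ids equal nucleus
    ids).  ``areas_px[k-1]`` is the pixel count of territory ``k``.
    """

    territories: np.ndarray
    pixel_size_um: float
    count: int = field(init=False)
    areas_px: np.ndarray = field(init=False)

    def __post_init__(self):
        terr = np.asarray(self.territories)
        if not np.issubdtype(terr.dtype, np.integer):
            raise ValidationError("territories must be integer-valued")
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be > 0")
        count = int(terr.max()) if terr.size else 0
        ids = np.arange(1, count + 1)
        areas = (
            ndi.sum_labels(np.ones_like(terr, dtype=np.int64), terr, ids)
            if count
            else np.zeros((0,))
        )
        object.__setattr__(self, "territories", terr)
        object.__setattr__(self, "count", count)
        object.__setattr__(self, "areas_px", areas.astype(np.int64))

    @property
    def areas_um2(self) -> np.ndarray:
        return self.areas_px * self.pixel_size_um**2

    def territory_ids(self) -> np.ndarray:
        return np.arange(1, self.count + 1)


def binarize_tumor_marker(
    tumor_channel: np.ndarray,
    method: str = "otsu",
    threshold: float | None = None,
    smoothing_sigma_um: float = 0.3,
    min_hole_um2: float = 30.0,
    pixel_size_um: float = 1.0,
) -> TumorMask:
    """Threshold the tumor-marker channel into a tissue mask.

    ``method`` is ``"otsu"`` or ``"fixed"`` (with ``threshold``).  The mask is
    ``smoothed >= threshold``, then holes smaller than ``min_hole_um2`` are
    filled.  Raising a fixed threshold never grows the mask.
    """
    img = np.asarray(tumor_channel, dtype=np.float64)
    if img.ndim != 2 or img.size == 0:
        raise ValidationError("tumor channel must be a nonempty 2D raster")
    if pixel_size_um <= 0:
        raise ValidationError("pixel_size_um must be > 0")
    smoothed = (
        ndi.gaussian_filter(img, smoothing_sigma_um / pixel_size_um)
        if smoothing_sigma_um > 0
        else img
    )
    if method == "fixed":
        if threshold is None:
            raise ValidationError("fixed thresholding requires a threshold value")
        thr = float(threshold)
    elif method == "otsu":
        if smoothed.max() == smoothed.min():
            warnings.warn("flat tumor channel: empty tumor mask")
            return TumorMask(np.zeros(img.shape, dtype=bool), float(smoothed.max()))
        thr = float(threshold_otsu(smoothed))
    else:
        raise ValidationError(f"unknown threshold method {method!r}")
    mask = smoothed >= thr
    min_hole_px = int(min_hole_um2 / pixel_size_um**2)
    if min_hole_px > 1 and mask.any():
        mask = remove_small_holes(mask, max_size=min_hole_px)
    return TumorMask(mask, thr)


def select_tumor_nuclei(
    nuclei: NucleiLabels,
    tumor: TumorMask,
    min_overlap_fraction: float = 0.5,
) -> NucleiLabels:
    """Keep nuclei encapsulated by the tumor tissue.

    A nucleus is retained iff the fraction of its pixels inside the tumor mask
    is ≥ ``min_overlap_fraction``; the default 0.5 reads "encapsulated" as
    majority-inside.  Survivors are relabeled consecutively.
    """
    if nuclei.labels.shape != tumor.mask.shape:
        raise ValidationError("nuclei and tumor rasters must share one shape")
    if not (0 <= min_overlap_fraction <= 1):
        raise ValidationError("min_overlap_fraction must be in [0, 1]")
    if nuclei.count == 0:
        return nuclei
    ids = np.arange(1, nuclei.count + 1)
    inside = ndi.sum_labels(tumor.mask.astype(np.int64), nuclei.labels, ids)
    frac = inside / nuclei.areas_px
    keep = frac >= min_overlap_fraction
    lut = np.zeros(nuclei.count + 1, dtype=np.int32)
    lut[1:][keep] = 1
    return NucleiLabels(canonical_relabel(lut[nuclei.labels] * nuclei.labels))


def voronoi_territories(
    tumor_nuclei: NucleiLabels,
    tumor: TumorMask,
    pixel_size_um: float = 1.0,
) -> CellMap:
    """Assign every tumor-mask pixel to its nearest nucleus instance.

    Distance is the Euclidean distance to the nearest pixel *of each
    instance* (generalized Voronoi of regions, reducing to the point diagram
    for point seeds).  Equidistant pixels go to the lower nucleus id.
    Squared distances are compared as exact integers, so the tie rule is
    bit-reproducible and matches a brute-force per-pixel search.
    """
    if tumor_nuclei.labels.shape != tumor.mask.shape:
        raise ValidationError("nuclei and tumor rasters must share one shape")
    if tumor_nuclei.count == 0:
        warnings.warn("no tumor nuclei: empty cell map")
        return CellMap(np.zeros(tumor.mask.shape, dtype=np.int32), pixel_size_um)

    shape = tumor.mask.shape
    rows, cols = np.indices(shape)
    best_d2 = np.full(shape, np.iinfo(np.int64).max, dtype=np.int64)
    territories = np.zeros(shape, dtype=np.int32)
    # iterate in increasing label order; strict '<' makes the lower id win ties
    for k in range(1, tumor_nuclei.count + 1):
        nearest = ndi.distance_transform_edt(
            tumor_nuclei.labels != k, return_distances=False, return_indices=True
        )
        d2 = (rows - nearest[0]).astype(np.int64) ** 2 + (
            cols - nearest[1]
        ).astype(np.int64) ** 2
        upd = d2 < best_d2
        territories[upd] = k
        best_d2[upd] = d2[upd]
    territories[~tumor.mask] = 0
    return CellMap(territories, pixel_size_um)
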