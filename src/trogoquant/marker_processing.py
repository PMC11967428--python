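"""Conditioning of the trogocytic-marker channel and the control-based gate.

Processing order is fixed: rolling-ball style background subtraction →
contrast-limited adaptive histogram equalization (CLAHE) → binarization.
The expression gate is a percentile of per-cell mean intensities measured on
secondary-antibody-only control fields, the imaging analog of an isotype/FMO
gate in flow cytometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.exposure import equalize_adapthist, equalize_hist
from skimage.filters import threshold_otsu
from skimage.morphology import disk, opening

from .errors import ValidationError

__all__ = [
    "MarkerMask",
    "ControlGate",
    "subtract_background",
    "clahe_normalize",
    "binarize_marker",
    "control_threshold",
]


@dataclass(frozen=True)
class MarkerMask:
    """Binary marker-positive mask plus the method record that produced it.

    The method record fully determines the mask given the input channel, so
    a mask is reproducible from its provenance alone.
    """

    mask: np.ndarray
    method: dict

    def __post_init__(self):
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))


@dataclass(frozen=True)
class ControlGate:
    """Expression gate derived from secondary-antibody-only control cells."""

    intensity_threshold: float
    percentile_used: float
    n_control_cells: int


def subtract_background(
    channel: np.ndarray,
    radius_um: float,
    pixel_size_um: float,
) -> np.ndarray:
    """Remove smooth background by morphological opening with a disk.

    The disk radius is ``radius_um / pixel_size_um`` pixels; the opening is
    an estimate of everything wider than the disk (shading, tissue glow) and
    is subtracted, clipping at zero.  A flat image maps to all zeros; features
    smaller than the disk pass through unchanged.  A decomposed (sequence)
    disk footprint keeps the operation fast at the large radii typical of
    background estimation.
    """
    img = np.asarray(channel, dtype=np.float64)
    if img.ndim != 2 or img.size == 0:
        raise ValidationError("channel must be a nonempty 2D raster")
    if pixel_size_um <= 0:
        raise ValidationError("pixel_size_um must be > 0")
    radius_px = radius_um / pixel_size_um
    if radius_px < 1:
        raise ValidationError(
            f"background radius {radius_um} µm is below one pixel "
            f"({pixel_size_um} µm); increase the radius"
        )
    footprint = disk(int(round(radius_px)), decomposition="sequence")
    background = opening(img, footprint=footprint)
    return np.clip(img - background, 0.0, None)


def clahe_normalize(
    channel: np.ndarray,
    tile_px: int = 64,
    clip_limit: float = 0.01,
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization, output in [0, 1].

    The channel is first rescaled to [0, 1] by its own range; tiles of
    ``tile_px`` pixels are equalized with clipped histograms and bilinear
    interpolation between tile centers.  A constant image returns all zeros
    (there is no contrast to amplify).  If the tile exceeds the image, the
    function falls back to global histogram equalization with a warning.
    """
    img = np.asarray(channel, dtype=np.float64)
    if img.ndim != 2 or img.size == 0:
        raise ValidationError("channel must be a nonempty 2D raster")
    if tile_px < 8:
        raise ValidationError("tile_px must be >= 8")
    if clip_limit <= 0:
        raise ValidationError("clip_limit must be > 0")
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        return np.zeros_like(img)
    scaled = (img - lo) / (hi - lo)
    if tile_px > min(img.shape):
        warnings.warn("CLAHE tile larger than image: using global equalization")
        return equalize_hist(scaled)
    return equalize_adapthist(scaled, kernel_size=tile_px, clip_limit=clip_limit, nbins=256)


def binarize_marker(
    channel: np.ndarray,
    method: str = "otsu",
    threshold: float | None = None,
    gate: ControlGate | None = None,
) -> MarkerMask:
    """Binarize the processed marker channel.

    ``method`` is ``"otsu"``, ``"fixed"`` (requires ``threshold``) or
    ``"control_gate"`` (requires ``gate``; uses its intensity threshold).
    The mask is ``channel >= threshold`` and the resolved threshold is stored
    in the method record.
    """
    img = np.asarray(channel, dtype=np.float64)
    if img.ndim != 2 or img.size == 0:
        raise ValidationError("channel must be a nonempty 2D raster")
    if method == "fixed":
        if threshold is None:
            raise ValidationError("fixed binarization requires a threshold value")
        thr = float(threshold)
    elif method == "otsu":
        if img.max() == img.min():
            warnings.warn("flat marker channel: empty marker mask")
            return MarkerMask(
                np.zeros(img.shape, dtype=bool),
                {"method": "otsu", "threshold": float(img.max()), "degenerate": True},
            )
        # nudge above the returned threshold so that `>=` matches skimage's
        # `img > thr` upper-class convention on discrete histograms
        thr = float(np.nextafter(threshold_otsu(img), np.inf))
    elif method == "control_gate":
        if gate is None:
            raise ValidationError("control_gate binarization requires a ControlGate")
        thr = float(gate.intensity_threshold)
    else:
        raise ValidationError(f"unknown binarization method {method!r}")
    return MarkerMask(img >= thr, {"method": method, "threshold": thr})


def control_threshold(
    control_cell_intensities: Sequence[float],
    percentile: float = 99.0,
) -> ControlGate:
    """Expression gate from per-cell mean intensities of control cells.

    The threshold is the given percentile (linear-interpolation definition,
    ``numpy.percentile``) of the control distribution.  At least 10 control
    cells are required; acquire more secondary-antibody-only fields otherwise.
    """
    values = np.asarray(list(control_cell_intensities), dtype=np.float64)
    if not (0 < percentile <= 100):
        raise ValidationError("percentile must be in (0, 100]")
    if values.size < 10:
        raise ValidationError(
            f"only {values.size} control cells; need >= 10 -- "
            "acquire more control fields"
        )
    thr = float(np.percentile(values, percentile))
    return ControlGate(thr, float(percentile), int(values.size))
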