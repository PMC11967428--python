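"""Detection and morphometry of trogosomes.

Trogosomes are intracellular spheres of donor-cell membrane coated with the
trogocytic marker; in a single imaging plane they appear as bright disks or,
more often, hollow rings.  Detection proceeds in three steps:

1. **Grayscale hole filling** by morphological reconstruction, which turns a
   marker-coated ring into a solid plateau while leaving filled disks
   untouched.  Scale selection on the raw ring image would lock onto the
   annulus thickness rather than the sphere diameter.
2. **Multiscale Laplacian-of-Gaussian (LoG) detection** over the diameter
   search range, with scale-normalized responses; candidate peaks below the
   response threshold are dropped, and overlapping candidates (center
   distance under half the smaller diameter) are merged keeping the
   stronger response.
3. **Diameter refinement** from the azimuthally averaged radial intensity
   profile around each detection: the equivalent-circle diameter is twice the
   radius where the profile falls to half of the plateau level.  The raw LoG
   estimate ``d = 2σ√2·pixel_size`` is kept as a fallback when the profile
   has no half-max crossing.

Detections must lie inside a cell territory and outside the owning cell's
nucleus, reflecting the observation that trogosomes sit beside (and deform)
the nucleus rather than within it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.morphology import reconstruction

from .errors import ValidationError
from .segmentation import NucleiLabels
from .tumor_map import CellMap

__all__ = [
    "TrogosomeRecord",
    "TimepointSummary",
    "detect_trogosomes",
    "hollowness",
    "summarize_timepoint",
    "trogosome_records_to_frame",
]


@dataclass(frozen=True)
class TrogosomeRecord:
    """One detected trogosome: owner cell, geometry, and hollowness."""

    source_id: str
    cell_id: int
    trogosome_id: int
    centroid_x_px: float
    centroid_y_px: float
    diameter_um: float
    is_large: bool
    hollowness: float | None = None
    response: float = 0.0

    def __post_init__(self):
        if not self.diameter_um > 0:
            raise ValidationError("diameter_um must be > 0")


@dataclass(frozen=True)
class TimepointSummary:
    """Per-timepoint cell counts and diameter statistics.

    A cell counts once toward ``n_cells_with_large_trogosome`` no matter how
    many large trogosomes it contains.  Diameter statistics are reported both
    per trogosome and as per-cell means, since either convention is found in
    practice.
    """

    timepoint: str
    n_cells: int
    n_cells_with_large_trogosome: int
    pct_with_large_trogosome: float | None
    mean_diameter_um: float | None
    sd_diameter_um: float | None
    n_trogosomes: int
    mean_per_cell_diameter_um: float | None
    empty: bool = False


def _circle_overlap(dist: float, r1: float, r2: float) -> float:
    """Fraction of the smaller circle's area covered by the larger one."""
    r_small, r_big = sorted((r1, r2))
    if dist >= r_small + r_big:
        return 0.0
    if dist <= r_big - r_small:
        return 1.0
    # lens area of two intersecting circles
    d2, rs2, rb2 = dist**2, r_small**2, r_big**2
    alpha = np.arccos(np.clip((d2 + rs2 - rb2) / (2 * dist * r_small), -1, 1))
    beta = np.arccos(np.clip((d2 + rb2 - rs2) / (2 * dist * r_big), -1, 1))
    lens = (
        rs2 * (alpha - np.sin(2 * alpha) / 2) + rb2 * (beta - np.sin(2 * beta) / 2)
    )
    return float(lens / (np.pi * rs2))


_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def _fill_holes_gray(img: np.ndarray) -> np.ndarray:
    """Fill grayscale holes: rings become plateaus, disks are unchanged.

    4-connected reconstruction, so one-pixel diagonal joints in a thin
    annulus still act as a closed barrier.
    """
    seed = img.copy()
    seed[1:-1, 1:-1] = img.max()
    return reconstruction(seed, img, method="erosion", footprint=_CROSS)


def _radial_half_max_radius(
    img: np.ndarray, cy: int, cx: int, r_guess_px: float
) -> float | None:
    """Radius where the azimuthal mean profile drops to half the plateau."""
    h, w = img.shape
    rmax = max(2.0 * r_guess_px, r_guess_px + 6.0)
    y0, y1 = max(0, int(cy - rmax - 1)), min(h, int(cy + rmax + 2))
    x0, x1 = max(0, int(cx - rmax - 1)), min(w, int(cx + rmax + 2))
    patch = img[y0:y1, x0:x1]
    yy, xx = np.indices(patch.shape)
    rho = np.hypot(yy - (cy - y0), xx - (cx - x0))
    step = 0.5
    edges = np.arange(0.0, rmax + step, step)
    prof = np.full(len(edges) - 1, np.nan)
    for j, a in enumerate(edges[:-1]):
        sel = (rho >= a) & (rho < a + step)
        if sel.any():
            prof[j] = patch[sel].mean()
    core_bins = max(2, int(0.4 * r_guess_px / step))
    core = np.nanmean(prof[:core_bins])
    bg = np.nanmin(prof)
    if not np.isfinite(core) or not np.isfinite(bg) or core <= bg:
        return None
    half = bg + 0.5 * (core - bg)
    centers = edges[:-1] + step / 2
    for j in range(len(prof) - 1):
        if np.isfinite(prof[j]) and np.isfinite(prof[j + 1]):
            if prof[j] >= half > prof[j + 1]:
                f = (prof[j] - half) / (prof[j] - prof[j + 1])
                return float(centers[j] + f * step)
    return None


def detect_trogosomes(
    marker_channel: np.ndarray,
    cells: CellMap,
    nuclei: NucleiLabels,
    diameter_range_um: tuple[float, float] = (1.5, 12.0),
    pixel_size_um: float | None = None,
    response_threshold: float = 0.08,
    large_cutoff_um: float = 5.0,
    source_id: str = "image",
    n_scales: int = 24,
) -> list[TrogosomeRecord]:
    """Detect trogosomes in the processed marker channel, one record each.

    ``diameter_range_um`` bounds the scale search; ``large_cutoff_um`` sets
    the strict ``is_large`` flag (``diameter > cutoff``).  Detections outside
    any territory or centered inside the owner's nucleus are discarded;
    overlapping detections are merged keeping the stronger LoG response.
    """
    d_lo, d_hi = diameter_range_um
    if not (0 < d_lo < d_hi):
        raise ValidationError("diameter range must be positive and ordered")
    if pixel_size_um is None:
        pixel_size_um = cells.pixel_size_um
    img = np.asarray(marker_channel, dtype=np.float64)
    if img.shape != cells.territories.shape:
        raise ValidationError("marker channel and cell map must share one shape")
    if cells.count == 0 or img.max() <= 0:
        return []
    img = img / img.max()
    filled = _fill_holes_gray(img)

    s = 2.0 * np.sqrt(2.0)  # d_px = s * sigma
    sig_lo = max(0.6, (d_lo / pixel_size_um) / s * 0.7)
    sig_hi = (d_hi / pixel_size_um) / s * 1.2
    sigmas = np.geomspace(sig_lo, sig_hi, n_scales)

    candidates = []  # (response, row, col, sigma)
    for sigma in sigmas:
        resp = -(sigma**2) * ndi.gaussian_laplace(filled, sigma)
        peaks = peak_local_max(
            resp, min_distance=max(1, int(sigma)), threshold_abs=response_threshold,
            exclude_border=False,
        )
        for r, c in peaks:
            candidates.append((float(resp[r, c]), int(r), int(c), float(sigma)))
    if not candidates:
        return []

    # strongest response first; a candidate is merged away when its center
    # falls within half the smaller diameter of a kept detection, or when
    # most of its circle lies inside a kept circle (ring-edge responses of a
    # larger sphere show up as small off-center blobs)
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    kept: list[tuple[float, int, int, float, float]] = []  # + diameter_px
    for resp, r, c, sigma in candidates:
        d_px_guess = s * sigma
        merged = False
        for resp0, r0, c0, sigma0, d0 in kept:
            dist = np.hypot(r - r0, c - c0)
            if dist < 0.5 * min(d_px_guess, d0):
                merged = True
                break
            if _circle_overlap(dist, d_px_guess / 2, d0 / 2) > 0.5:
                merged = True
                break
        if not merged:
            kept.append((resp, r, c, sigma, d_px_guess))

    records = []
    tid = 0
    for resp, r, c, sigma, d_px_guess in kept:
        owner = int(cells.territories[r, c])
        if owner == 0:
            continue
        if nuclei.labels[r, c] == owner:  # centered inside the owning nucleus
            continue
        r_half = _radial_half_max_radius(filled, r, c, d_px_guess / 2)
        d_px = 2 * r_half if r_half is not None else d_px_guess
        d_um = d_px * pixel_size_um
        if not (d_lo * 0.5 <= d_um <= d_hi * 1.5):
            continue
        tid += 1
        records.append(
            TrogosomeRecord(
                source_id=source_id,
                cell_id=owner,
                trogosome_id=tid,
                centroid_x_px=float(c),
                centroid_y_px=float(r),
                diameter_um=float(d_um),
                is_large=bool(d_um > large_cutoff_um),
                hollowness=_hollowness_at(img, r, c, d_px / 2),
                response=resp,
            )
        )
    return records


def hollowness(
    marker_channel: np.ndarray,
    record: TrogosomeRecord,
    pixel_size_um: float,
) -> float | None:
    """Central-to-ring intensity ratio; values < 1 indicate a hollow sphere.

    Mean intensity in the central disk (radius 0.4 r) divided by the mean in
    the 0.7–1.0 r annulus, where r is the record's radius in pixels of the
    supplied raster.  Returns None (flagged degenerate) when the radius is
    under 2 px.
    """
    img = np.asarray(marker_channel, dtype=np.float64)
    cy, cx = record.centroid_y_px, record.centroid_x_px
    if not (0 <= cy < img.shape[0] and 0 <= cx < img.shape[1]):
        raise ValidationError("record centroid lies outside the image")
    radius_px = record.diameter_um / (2 * pixel_size_um)
    return _hollowness_at(img, cy, cx, radius_px)


def _hollowness_at(img: np.ndarray, cy: float, cx: float, radius_px: float | None) -> float | None:
    if radius_px is None or radius_px < 2:
        warnings.warn("degenerate trogosome radius (< 2 px): hollowness is null")
        return None
    h, w = img.shape
    rmax = int(np.ceil(radius_px)) + 1
    y0, y1 = max(0, int(cy) - rmax), min(h, int(cy) + rmax + 1)
    x0, x1 = max(0, int(cx) - rmax), min(w, int(cx) + rmax + 1)
    patch = img[y0:y1, x0:x1]
    yy, xx = np.indices(patch.shape)
    rho = np.hypot(yy - (cy - y0), xx - (cx - x0))
    center = patch[rho <= 0.4 * radius_px]
    ring = patch[(rho >= 0.7 * radius_px) & (rho <= radius_px)]
    if center.size == 0 or ring.size == 0 or ring.mean() <= 0:
        warnings.warn("degenerate trogosome geometry: hollowness is null")
        return None
    return float(center.mean() / ring.mean())


def summarize_timepoint(
    records: Iterable[TrogosomeRecord],
    cells: CellMap,
    timepoint: str,
    large_cutoff_um: float = 5.0,
) -> TimepointSummary:
    """Fraction of cells containing a large trogosome, plus diameter stats.

    ``is_large`` is re-evaluated against ``large_cutoff_um`` (strictly
    greater), so the summary stays consistent under a cutoff override.
    """
    records = list(records)
    n_cells = cells.count
    if n_cells == 0:
        warnings.warn("zero cells: null timepoint summary")
        return TimepointSummary(timepoint, 0, 0, None, None, None, 0, None, empty=True)
    for rec in records:
        if not (1 <= rec.cell_id <= n_cells):
            raise ValidationError(f"record references unknown cell {rec.cell_id}")
    diams = np.array([r.diameter_um for r in records])
    large_owners = {r.cell_id for r in records if r.diameter_um > large_cutoff_um}
    per_cell = pd.Series(diams, index=[r.cell_id for r in records]) if records else None
    mean_per_cell = (
        float(per_cell.groupby(level=0).mean().mean()) if records else None
    )
    return TimepointSummary(
        timepoint=timepoint,
        n_cells=n_cells,
        n_cells_with_large_trogosome=len(large_owners),
        pct_with_large_trogosome=100.0 * len(large_owners) / n_cells,
        mean_diameter_um=float(diams.mean()) if records else None,
        sd_diameter_um=float(diams.std(ddof=1)) if len(records) > 1 else None,
        n_trogosomes=len(records),
        mean_per_cell_diameter_um=mean_per_cell,
    )


def trogosome_records_to_frame(records: Iterable[TrogosomeRecord]) -> pd.DataFrame:
    records = list(records)
    if not records:
        return pd.DataFrame()
    return pd.DataFrame([vars(r) for r in records]).drop(columns=["response"])
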