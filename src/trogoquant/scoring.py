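"""Per-cell marker coverage, the trogocytosis flag, and sample summaries.

A tumor cell is flagged trogocytic when the marker-positive fraction of its
Voronoi territory lies strictly between the lower and upper coverage bounds
(defaults 0.55 and 0.90).  The lower bound rejects sparse or incidental
staining; the upper bound discards cells whose apparent coverage is driven by
autofluorescence or bright anomalies such as paraffin debris.  Both bounds are
strict: coverage exactly at a bound is not flagged.

"Surface area of a tumor cell" here means the area of its 2D Voronoi
territory — the flag's denominator — because no membrane stain exists in this
assay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .errors import ValidationError
from .marker_processing import ControlGate, MarkerMask
from .segmentation import NucleiLabels
from .tumor_map import CellMap

__all__ = [
    "CellRecord",
    "SampleResult",
    "coverage_fraction",
    "flag_trogocytic",
    "score_cells",
    "summarize_sample",
    "summarize_groups",
    "cell_records_to_frame",
    "sample_results_to_frame",
]


@dataclass(frozen=True)
class CellRecord:
    """One tumor cell: geometry, marker intensity, coverage, and flags."""

    source_id: str
    cell_id: int
    centroid_x_px: float
    centroid_y_px: float
    territory_area_um2: float
    mean_marker_intensity: float
    coverage_fraction: float
    expresses_marker: bool
    is_trogocytic: bool
    touches_border: bool = False

    def __post_init__(self):
        if not (0 <= self.coverage_fraction <= 1):
            raise ValidationError("coverage_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SampleResult:
    """Per-sample counts and percentages; ``empty`` flags n_tumor_cells == 0."""

    source_id: str
    group: str
    n_tumor_cells: int
    n_expressing: int
    pct_expressing: float | None
    n_trogocytic: int
    pct_trogocytic: float | None
    empty: bool = False


def coverage_fraction(cells: CellMap, marker: MarkerMask) -> np.ndarray:
    """Marker-positive pixel fraction of each territory.

    Returns an array indexed so entry ``k - 1`` is territory ``k``'s
    fraction: ``|marker ∧ territory_k| / |territory_k|``, an exact ratio of
    integer pixel counts divided once.
    """
    if cells.territories.shape != marker.mask.shape:
        raise ValidationError("cell map and marker mask must share one shape")
    if cells.count == 0:
        return np.zeros((0,))
    if (cells.areas_px == 0).any():
        raise ValidationError("territory with zero pixels: invalid CellMap")
    ids = cells.territory_ids()
    positive = ndi.sum_labels(marker.mask.astype(np.int64), cells.territories, ids)
    return positive / cells.areas_px


def flag_trogocytic(coverage, low: float = 0.55, high: float = 0.90):
    """True iff ``low < coverage < high`` — strict on both ends.

    Scalar in, scalar out; array in, boolean array out.
    """
    if not (0 <= low < high <= 1):
        raise ValidationError("need 0 <= low < high <= 1")
    cov = np.asarray(coverage)
    result = (cov > low) & (cov < high)
    return bool(result) if np.isscalar(coverage) else result


def _touches_border(territories: np.ndarray, ids: np.ndarray) -> np.ndarray:
    edge = np.concatenate(
        [territories[0], territories[-1], territories[:, 0], territories[:, -1]]
    )
    edge_ids = np.unique(edge)
    return np.isin(ids, edge_ids)


def score_cells(
    cells: CellMap,
    nuclei: NucleiLabels,
    marker: MarkerMask,
    processed_channel: np.ndarray,
    source_id: str,
    gate: ControlGate | None = None,
    low: float = 0.55,
    high: float = 0.90,
    exclude_border_cells: bool = False,
) -> list[CellRecord]:
    """Build one CellRecord per tumor cell.

    Mean marker intensity is taken from the processed channel within the
    territory; ``expresses_marker`` compares that mean against the control
    gate (False for every cell when no gate is supplied).  Cells whose
    territory touches the image border are marked — their truncated territory
    biases coverage — and dropped only if ``exclude_border_cells``.
    """
    cov = coverage_fraction(cells, marker)
    ids = cells.territory_ids()
    if cells.count == 0:
        return []
    processed = np.asarray(processed_channel, dtype=np.float64)
    means = ndi.mean(processed, cells.territories, ids)
    flags = flag_trogocytic(cov, low, high)
    border = _touches_border(cells.territories, ids)
    expressing = (
        means > gate.intensity_threshold if gate is not None else np.zeros(len(ids), bool)
    )
    records = []
    for i, k in enumerate(ids):
        if exclude_border_cells and border[i]:
            continue
        cy, cx = nuclei.centroids[k - 1]
        records.append(
            CellRecord(
                source_id=source_id,
                cell_id=int(k),
                centroid_x_px=float(cx),
                centroid_y_px=float(cy),
                territory_area_um2=float(cells.areas_um2[i]),
                mean_marker_intensity=float(means[i]),
                coverage_fraction=float(cov[i]),
                expresses_marker=bool(expressing[i]),
                is_trogocytic=bool(flags[i]),
                touches_border=bool(border[i]),
            )
        )
    return records


def summarize_sample(records: Iterable[CellRecord], group: str = "") -> SampleResult:
    """Aggregate cell records of one sample into counts and percentages."""
    records = list(records)
    if not records:
        warnings.warn("empty record set: null sample result")
        return SampleResult("", group, 0, 0, None, 0, None, empty=True)
    source_ids = {r.source_id for r in records}
    if len(source_ids) != 1:
        raise ValidationError(f"records mix source_ids: {sorted(source_ids)}")
    n = len(records)
    n_exp = sum(r.expresses_marker for r in records)
    n_trog = sum(r.is_trogocytic for r in records)
    return SampleResult(
        source_id=records[0].source_id,
        group=group,
        n_tumor_cells=n,
        n_expressing=n_exp,
        pct_expressing=100.0 * n_exp / n,
        n_trogocytic=n_trog,
        pct_trogocytic=100.0 * n_trog / n,
    )


def summarize_groups(samples: Sequence[SampleResult]) -> pd.DataFrame:
    """Per-group sample count, mean and sd of the two percentage endpoints.

    Returns a tidy table (one row per group) ready for downstream statistics;
    sd is the sample standard deviation (ddof=1), null for singleton groups.
    """
    frame = sample_results_to_frame(samples)
    if frame.empty:
        return pd.DataFrame(
            columns=[
                "group",
                "n_samples",
                "mean_pct_expressing",
                "sd_pct_expressing",
                "mean_pct_trogocytic",
                "sd_pct_trogocytic",
            ]
        )
    grouped = frame.groupby("group", sort=True)
    out = grouped.agg(
        n_samples=("source_id", "size"),
        mean_pct_expressing=("pct_expressing", "mean"),
        sd_pct_expressing=("pct_expressing", lambda s: s.std(ddof=1)),
        mean_pct_trogocytic=("pct_trogocytic", "mean"),
        sd_pct_trogocytic=("pct_trogocytic", lambda s: s.std(ddof=1)),
    )
    return out.reset_index()


def cell_records_to_frame(records: Iterable[CellRecord]) -> pd.DataFrame:
    records = list(records)
    if not records:
        return pd.DataFrame()
    return pd.DataFrame([vars(r) for r in records])


def sample_results_to_frame(samples: Iterable[SampleResult]) -> pd.DataFrame:
    samples = list(samples)
    if not samples:
        return pd.DataFrame()
    return pd.DataFrame([vars(s) for s in samples])
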