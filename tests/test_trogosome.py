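"""Trogosome detection, diameter and hollowness morphometry, summaries."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from trogoquant import (
    NucleiLabels,
    PipelineConfig,
    SyntheticParams,
    detect_trogosomes,
    generate_coculture_field,
    hollowness,
    summarize_timepoint,
    trogosome_image,
)
from trogoquant.tumor_map import CellMap
from trogoquant.trogosome import TrogosomeRecord

PX = 0.25


def _record(d_um, cell_id=1, cy=50.0, cx=50.0, large_cutoff=5.0):
    return TrogosomeRecord(
        source_id="s",
        cell_id=cell_id,
        trogosome_id=1,
        centroid_x_px=cx,
        centroid_y_px=cy,
        diameter_um=d_um,
        is_large=d_um > large_cutoff,
    )


def _single_cell_map(shape=(100, 100)):
    return CellMap(np.ones(shape, dtype=np.int32), PX)


class TestDetectTrogosomes:
    def test_blank_channel_no_detections(self):
        cells = _single_cell_map()
        nuclei = NucleiLabels(np.zeros((100, 100), dtype=np.int32))
        assert detect_trogosomes(np.zeros((100, 100)), cells, nuclei) == []

    def test_empty_cellmap_no_detections(self):
        cells = CellMap(np.zeros((50, 50), dtype=np.int32), PX)
        nuclei = NucleiLabels(np.zeros((50, 50), dtype=np.int32))
        img = np.zeros((50, 50))
        img[20:25, 20:25] = 1.0
        assert detect_trogosomes(img, cells, nuclei) == []

    def test_single_six_micron_ring(self):
        params = SyntheticParams.coculture(
            shape=(320, 320), n_tumor_cells=4, trog_diameters_um=(6.0,), seed=41
        ).noiseless()
        image, truth = generate_coculture_field(params)
        cfg = PipelineConfig(tumor_threshold_method="fixed", tumor_threshold_value=0.0)
        records, _, _ = trogosome_image(
            image, cfg, nuclei_labels=NucleiLabels(truth.nuclei_labels)
        )
        assert len(records) == 1
        rec = records[0]
        assert abs(rec.diameter_um - 6.0) <= 0.6
        assert rec.is_large

    def test_diameter_set_and_large_count(self, coculture_grid, coculture_config):
        image, truth = coculture_grid
        records, summary, _ = trogosome_image(
            image, coculture_config, nuclei_labels=NucleiLabels(truth.nuclei_labels)
        )
        assert len(records) == 4  # one per planted {2, 4, 5.5, 8} µm
        assert sum(r.is_large for r in records) == 2
        gt = {t["owner"]: t["diameter_um"] for t in truth.trogosomes}
        for rec in records:
            planted = gt[rec.cell_id]
            assert abs(rec.diameter_um - planted) <= max(0.1 * planted, PX)

    def test_detection_lies_inside_territory_outside_nucleus(self, coculture_grid, coculture_config):
        image, truth = coculture_grid
        records, _, cells = trogosome_image(
            image, coculture_config, nuclei_labels=NucleiLabels(truth.nuclei_labels)
        )
        for rec in records:
            r, c = int(rec.centroid_y_px), int(rec.centroid_x_px)
            assert cells.territories[r, c] == rec.cell_id
            assert truth.nuclei_labels[r, c] != rec.cell_id


class TestHollowness:
    def test_uniform_disk_ratio_one(self):
        img = np.zeros((64, 64))
        yy, xx = np.indices((64, 64))
        img[(yy - 32) ** 2 + (xx - 32) ** 2 <= 12**2] = 0.8
        rec = _record(d_um=2 * 12 * PX, cy=32, cx=32)
        assert hollowness(img, rec, PX) == pytest.approx(1.0)

    def test_perfect_ring_zero_interior(self):
        img = np.zeros((64, 64))
        yy, xx = np.indices((64, 64))
        rho2 = (yy - 32) ** 2 + (xx - 32) ** 2
        img[(rho2 > (0.7 * 12) ** 2) & (rho2 <= 12**2)] = 1.0
        rec = _record(d_um=2 * 12 * PX, cy=32, cx=32)
        assert hollowness(img, rec, PX) == pytest.approx(0.0)

    def test_planted_hollow_fraction_recovered(self, coculture_grid, coculture_config):
        image, truth = coculture_grid
        records, _, _ = trogosome_image(
            image, coculture_config, nuclei_labels=NucleiLabels(truth.nuclei_labels)
        )
        for rec in records:
            if rec.diameter_um >= 4.0:  # thin small rings blur toward uniform
                assert rec.hollowness == pytest.approx(0.30, abs=0.05)

    def test_degenerate_radius_null(self):
        img = np.ones((32, 32))
        rec = _record(d_um=0.5, cy=16, cx=16)  # < 2 px radius at 0.25 µm/px
        with pytest.warns(UserWarning, match="degenerate"):
            assert hollowness(img, rec, PX) is None


class TestSummarizeTimepoint:
    def test_no_records_pct_zero(self):
        summary = summarize_timepoint([], _single_cell_map(), "4h")
        assert summary.pct_with_large_trogosome == 0.0
        assert summary.n_trogosomes == 0

    def test_every_cell_large_pct_hundred(self):
        terr = np.repeat(np.arange(1, 6, dtype=np.int32), 20).reshape(10, 10)
        cells = CellMap(terr, PX)
        records = [_record(7.0, cell_id=k) for k in range(1, 6)]
        summary = summarize_timepoint(records, cells, "16h")
        assert summary.pct_with_large_trogosome == 100.0

    def test_cell_counted_once_despite_multiple_large(self):
        cells = _single_cell_map()
        records = [_record(7.0), _record(8.0)]
        summary = summarize_timepoint(records, cells, "16h")
        assert summary.n_cells_with_large_trogosome == 1

    def test_exact_five_micron_never_large(self):
        cells = _single_cell_map()
        records = [_record(5.0) for _ in range(3)]
        summary = summarize_timepoint(records, cells, "8h", large_cutoff_um=5.0)
        assert summary.pct_with_large_trogosome == 0.0
        assert not any(r.is_large for r in records)

    def test_raising_cutoff_never_increases_pct(self):
        rng = np.random.default_rng(6)
        terr = np.repeat(np.arange(1, 11, dtype=np.int32), 10).reshape(10, 10)
        cells = CellMap(terr, PX)
        records = [
            _record(float(rng.uniform(1, 10)), cell_id=int(rng.integers(1, 11)))
            for _ in range(30)
        ]
        pcts = [
            summarize_timepoint(records, cells, "t", cutoff).pct_with_large_trogosome
            for cutoff in np.linspace(1.0, 10.0, 10)
        ]
        assert all(a >= b for a, b in zip(pcts, pcts[1:]))

    def test_zero_cells_flagged_null(self):
        cells = CellMap(np.zeros((10, 10), dtype=np.int32), PX)
        with pytest.warns(UserWarning, match="zero cells"):
            summary = summarize_timepoint([], cells, "4h")
        assert summary.empty
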