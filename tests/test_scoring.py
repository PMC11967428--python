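"""Coverage arithmetic, the strict flag window, and sample/group summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trogoquant import (
    NucleiLabels,
    PipelineConfig,
    SyntheticParams,
    ValidationError,
    coverage_fraction,
    flag_trogocytic,
    generate_ffpe_field,
    quantify_image,
    summarize_groups,
    summarize_sample,
)
from trogoquant.marker_processing import MarkerMask
from trogoquant.scoring import CellRecord
from trogoquant.tumor_map import CellMap


def _cellmap_10x10():
    terr = np.zeros((10, 20), dtype=np.int32)
    terr[:, :10] = 1
    terr[:, 10:] = 2
    return CellMap(terr, 0.2)


def _mask(arr):
    return MarkerMask(arr, {"method": "fixed", "threshold": 0.5})


class TestCoverageFraction:
    def test_all_true_mask(self):
        cells = _cellmap_10x10()
        cov = coverage_fraction(cells, _mask(np.ones((10, 20), bool)))
        np.testing.assert_array_equal(cov, [1.0, 1.0])

    def test_all_false_mask(self):
        cells = _cellmap_10x10()
        cov = coverage_fraction(cells, _mask(np.zeros((10, 20), bool)))
        np.testing.assert_array_equal(cov, [0.0, 0.0])

    def test_exact_integer_ratio(self):
        cells = _cellmap_10x10()
        mask = np.zeros((10, 20), dtype=bool)
        mask.ravel()[np.random.default_rng(0).permutation(200)[:60]] = True
        # territory 1 occupies columns 0..9; count its positives exactly
        n1 = mask[:, :10].sum()
        cov = coverage_fraction(cells, _mask(mask))
        assert cov[0] == n1 / 100

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            coverage_fraction(_cellmap_10x10(), _mask(np.ones((5, 5), bool)))


class TestFlagTrogocytic:
    @pytest.mark.parametrize(
        "coverage,expected",
        [(0.55, False), (0.90, False), (0.70, True), (0.551, True), (0.899, True), (0.0, False), (1.0, False)],
    )
    def test_strict_bounds(self, coverage, expected):
        assert flag_trogocytic(coverage) is expected

    def test_invalid_window_rejected(self):
        with pytest.raises(ValidationError):
            flag_trogocytic(0.5, low=0.9, high=0.5)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        data=st.data(),
        low=st.floats(0.0, 0.5),
        width=st.floats(0.01, 0.5),
    )
    def test_widening_window_never_decreases_count(self, data, low, width):
        high = min(1.0, low + width)
        coverages = np.array(
            data.draw(st.lists(st.floats(0, 1), min_size=1, max_size=50))
        )
        inner = flag_trogocytic(coverages, low, high).sum()
        wider_low = max(0.0, low - 0.05)
        wider_high = min(1.0, high + 0.05)
        outer = flag_trogocytic(coverages, wider_low, wider_high).sum()
        assert outer >= inner


def _records(n, n_expressing, n_trog, source="s"):
    recs = []
    for i in range(n):
        recs.append(
            CellRecord(
                source_id=source,
                cell_id=i + 1,
                centroid_x_px=0.0,
                centroid_y_px=0.0,
                territory_area_um2=10.0,
                mean_marker_intensity=0.1,
                coverage_fraction=0.7 if i < n_trog else 0.1,
                expresses_marker=i < n_expressing,
                is_trogocytic=i < n_trog,
            )
        )
    return recs


class TestSummarizeSample:
    def test_percentages(self):
        result = summarize_sample(_records(100, 42, 10), group="II")
        assert result.pct_expressing == 42.0
        assert result.pct_trogocytic == 10.0
        assert result.group == "II"

    def test_empty_is_flagged_null(self):
        with pytest.warns(UserWarning, match="empty"):
            result = summarize_sample([])
        assert result.empty and result.n_tumor_cells == 0
        assert result.pct_expressing is None

    def test_mixed_sources_rejected(self):
        records = _records(2, 0, 0, "a") + _records(2, 0, 0, "b")
        with pytest.raises(ValidationError, match="source"):
            summarize_sample(records)

    def test_conservation(self, ffpe_noiseless, gt_nuclei):
        image, _ = ffpe_noiseless
        result = quantify_image(image, PipelineConfig(), nuclei_labels=gt_nuclei)
        s = result.sample
        assert s.n_expressing <= s.n_tumor_cells
        assert s.n_trogocytic <= s.n_tumor_cells


class TestSummarizeGroups:
    def test_singleton_group_mean_no_sd(self):
        table = summarize_groups([summarize_sample(_records(10, 5, 2), "I")])
        row = table.iloc[0]
        assert row["mean_pct_expressing"] == 50.0
        assert np.isnan(row["sd_pct_expressing"])

    def test_identical_samples_zero_sd(self):
        samples = [
            summarize_sample(_records(10, 5, 2, "a"), "I"),
            summarize_sample(_records(10, 5, 2, "b"), "I"),
        ]
        table = summarize_groups(samples)
        assert table.iloc[0]["sd_pct_trogocytic"] == 0.0

    def test_planted_group_means_recovered(self):
        # 4 groups of small samples with planted trogocytic-coverage rates;
        # compare against the realized planted rate of each group
        group_fracs = {"I": 0.20, "II": 0.35, "III": 0.50, "IV": 0.60}
        samples, planted_means = [], {}
        seed = 100
        for group, frac in group_fracs.items():
            planted = []
            for _ in range(3):
                seed += 1
                rng = np.random.default_rng(seed)
                n = 40
                inside = rng.random(n) < frac
                coverages = tuple(
                    float(rng.uniform(0.60, 0.85)) if t else float(rng.uniform(0.0, 0.5))
                    for t in inside
                )
                params = SyntheticParams(
                    shape=(384, 384), n_tumor_cells=n, n_stromal_cells=0,
                    coverage_values=coverages, seed=seed,
                ).noiseless()
                image, truth = generate_ffpe_field(params)
                result = quantify_image(
                    image, PipelineConfig(), nuclei_labels=NucleiLabels(truth.nuclei_labels)
                )
                samples.append(summarize_sample(result.records, group))
                planted.append(100.0 * inside.mean())
            planted_means[group] = np.mean(planted)
        table = summarize_groups(samples).set_index("group")
        for group, expected in planted_means.items():
            assert abs(table.loc[group, "mean_pct_trogocytic"] - expected) <= 3.0
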