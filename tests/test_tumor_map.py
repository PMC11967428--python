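"""Tumor masking, nucleus selection, and Voronoi territories vs brute force."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trogoquant import (
    NucleiLabels,
    SyntheticParams,
    binarize_tumor_marker,
    generate_ffpe_field,
    select_tumor_nuclei,
    voronoi_territories,
)
from trogoquant.tumor_map import TumorMask


def brute_force_territories(labels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-pixel nearest-instance search with exact integer squared distances.

    The independent oracle: for every mask pixel, scan all instances and all
    their pixels; the minimal squared distance wins, ties to the lower id.
    """
    out = np.zeros_like(labels)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    instance_pixels = {k: np.argwhere(labels == k) for k in ids}
    for r, c in np.argwhere(mask):
        best_d2, best_k = None, 0
        for k in ids:
            pix = instance_pixels[k]
            d2 = int(((pix - (r, c)) ** 2).sum(axis=1).min())
            if best_d2 is None or d2 < best_d2:  # strict: lower id wins ties
                best_d2, best_k = d2, int(k)
        out[r, c] = best_k
    return out


def _random_fixture(rng, size=None, n_nuclei=None):
    h = size or rng.integers(16, 64)
    w = size or rng.integers(16, 64)
    n = n_nuclei or rng.integers(1, 11)
    labels = np.zeros((h, w), dtype=np.int32)
    yy, xx = np.indices((h, w))
    placed = 0
    for _ in range(200):
        if placed == n:
            break
        cy, cx = rng.integers(0, h), rng.integers(0, w)
        r = rng.integers(1, 4)
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        if (labels[disk] == 0).all() and disk.any():
            placed += 1
            labels[disk] = placed
    mask = rng.random((h, w)) < rng.uniform(0.3, 1.0)
    return labels, mask


class TestBinarizeTumorMarker:
    def test_fixed_zero_threshold_all_true(self):
        img = np.full((32, 32), 0.4)
        tm = binarize_tumor_marker(img, "fixed", threshold=0.0, smoothing_sigma_um=0)
        assert tm.mask.all() and tm.area_px == 32 * 32

    def test_fixed_above_max_all_false(self):
        img = np.random.default_rng(0).random((32, 32))
        tm = binarize_tumor_marker(img, "fixed", threshold=2.0, smoothing_sigma_um=0)
        assert not tm.mask.any()

    def test_flat_otsu_empty_with_warning(self):
        with pytest.warns(UserWarning, match="flat"):
            tm = binarize_tumor_marker(np.ones((16, 16)), "otsu")
        assert tm.area_px == 0

    def test_raising_fixed_threshold_never_grows_mask(self):
        rng = np.random.default_rng(1)
        img = rng.random((48, 48))
        prev = None
        for thr in np.linspace(0, 1, 7):
            mask = binarize_tumor_marker(
                img, "fixed", threshold=thr, smoothing_sigma_um=0, min_hole_um2=0
            ).mask
            if prev is not None:
                assert not (mask & ~prev).any()
            prev = mask

    def test_generator_mask_jaccard(self, ffpe_noiseless):
        image, truth = ffpe_noiseless
        tm = binarize_tumor_marker(
            image.channel("tumor_marker"), "otsu", pixel_size_um=image.pixel_size_um
        )
        inter = (tm.mask & truth.tumor_mask).sum()
        union = (tm.mask | truth.tumor_mask).sum()
        assert inter / union >= 0.99


class TestSelectTumorNuclei:
    def test_zero_overlap_fraction_is_identity(self, gt_nuclei):
        mask = TumorMask(np.zeros(gt_nuclei.shape, dtype=bool), 0.0)
        out = select_tumor_nuclei(gt_nuclei, mask, min_overlap_fraction=0.0)
        assert out.count == gt_nuclei.count

    def test_empty_mask_removes_all(self, gt_nuclei):
        mask = TumorMask(np.zeros(gt_nuclei.shape, dtype=bool), 0.0)
        assert select_tumor_nuclei(gt_nuclei, mask, 0.5).count == 0

    def test_planted_tumor_stromal_split(self):
        params = SyntheticParams(
            shape=(384, 384), n_tumor_cells=12, n_stromal_cells=8, seed=9
        ).noiseless()
        _, truth = generate_ffpe_field(params)
        nuclei = NucleiLabels(truth.nuclei_labels)
        out = select_tumor_nuclei(nuclei, TumorMask(truth.tumor_mask, 0.0), 0.5)
        assert nuclei.count == 20 and out.count == 12


class TestVoronoiTerritories:
    def test_single_nucleus_claims_whole_mask(self):
        labels = np.zeros((32, 32), dtype=np.int32)
        labels[10:13, 10:13] = 1
        mask = np.random.default_rng(2).random((32, 32)) < 0.7
        cells = voronoi_territories(NucleiLabels(labels), TumorMask(mask, 0.0), 0.2)
        np.testing.assert_array_equal(cells.territories > 0, mask)
        assert cells.count == 1

    def test_two_point_seeds_split_at_bisector(self):
        labels = np.zeros((21, 41), dtype=np.int32)
        labels[10, 10] = 1
        labels[10, 30] = 2
        mask = np.ones((21, 41), dtype=bool)
        cells = voronoi_territories(NucleiLabels(labels), TumorMask(mask, 0.0), 1.0)
        assert (cells.territories[:, :20] == 1).all()
        assert (cells.territories[:, 21:] == 2).all()
        assert (cells.territories[:, 20] == 1).all()  # tie column -> lower id

    def test_zero_nuclei_empty_map_with_warning(self):
        empty = NucleiLabels(np.zeros((16, 16), dtype=np.int32))
        with pytest.warns(UserWarning, match="no tumor nuclei"):
            cells = voronoi_territories(empty, TumorMask(np.ones((16, 16), bool), 0.0), 0.2)
        assert cells.count == 0

    def test_partition_sums_to_mask_area(self, ffpe_noiseless):
        _, truth = ffpe_noiseless
        assert (truth.territories > 0).sum() == truth.tumor_mask.sum()

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_brute_force_nearest_instance(self, seed):
        rng = np.random.default_rng(seed)
        labels, mask = _random_fixture(rng)
        if labels.max() == 0:
            return
        cells = voronoi_territories(NucleiLabels(labels), TumorMask(mask, 0.0), 1.0)
        expected = brute_force_territories(labels, mask)
        np.testing.assert_array_equal(cells.territories, expected)

    def test_shrinking_mask_never_grows_territories(self):
        rng = np.random.default_rng(5)
        labels, mask = _random_fixture(rng, size=48, n_nuclei=5)
        nuclei = NucleiLabels(labels)
        big = voronoi_territories(nuclei, TumorMask(mask, 0.0), 1.0)
        small_mask = mask & (rng.random(mask.shape) < 0.8)
        small = voronoi_territories(nuclei, TumorMask(small_mask, 0.0), 1.0)
        grown = (small.territories != 0) & (small.territories != big.territories)
        assert not grown.any()
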