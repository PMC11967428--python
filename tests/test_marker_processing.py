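"""Marker conditioning: background subtraction, CLAHE, binarization, gate."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from trogoquant import (
    NucleiLabels,
    SyntheticParams,
    ValidationError,
    binarize_marker,
    clahe_normalize,
    control_threshold,
    coverage_fraction,
    generate_ffpe_field,
    subtract_background,
)
from trogoquant.marker_processing import ControlGate
from trogoquant.tumor_map import CellMap

PX = 0.2


class TestSubtractBackground:
    def test_constant_image_maps_to_zero(self):
        out = subtract_background(np.full((64, 64), 7.0), radius_um=2.0, pixel_size_um=PX)
        np.testing.assert_array_equal(out, 0.0)

    def test_small_bright_spot_preserved(self):
        img = np.zeros((64, 64))
        img[30, 30:32] = 5.0
        out = subtract_background(img, radius_um=5.0, pixel_size_um=PX)
        assert abs(out[30, 30] - 5.0) <= 0.05
        assert abs(out[30, 31] - 5.0) <= 0.05

    def test_subpixel_radius_rejected(self):
        with pytest.raises(ValidationError, match="radius"):
            subtract_background(np.zeros((8, 8)), radius_um=0.1, pixel_size_um=PX)

    def test_linear_shading_removed(self):
        # planted gradient plus sparse foreground spots of amplitude 1
        yy, xx = np.indices((128, 128))
        gradient = 0.3 * xx / 127
        rng = np.random.default_rng(3)
        spots = np.zeros((128, 128))
        spots[rng.integers(0, 128, 200), rng.integers(0, 128, 200)] = 1.0
        out = subtract_background(gradient + spots, radius_um=10.0, pixel_size_um=PX)
        background = out[spots == 0]
        assert background.mean() < 0.05  # < 5% of foreground amplitude

    def test_idempotent_on_flat_background_output(self):
        img = np.zeros((64, 64))
        img[20:24, 20:24] = 2.0
        once = subtract_background(img, 5.0, PX)
        twice = subtract_background(once, 5.0, PX)
        assert np.abs(twice - once).max() <= 1e-9


class TestClaheNormalize:
    def test_constant_image_stays_constant(self):
        out = clahe_normalize(np.full((64, 64), 3.0))
        assert out.min() == out.max()

    def test_output_range_contract(self):
        rng = np.random.default_rng(0)
        out = clahe_normalize(rng.normal(50, 20, (128, 128)), tile_px=32)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_tile_larger_than_image_falls_back(self):
        img = np.random.default_rng(1).random((32, 32))
        with pytest.warns(UserWarning, match="tile"):
            out = clahe_normalize(img, tile_px=64)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_dim_and_bright_halves_both_stretched(self):
        rng = np.random.default_rng(2)
        img = np.empty((128, 128))
        img[:, :64] = rng.uniform(0.0, 0.1, (128, 64))   # dim half
        img[:, 64:] = rng.uniform(0.6, 1.0, (128, 64))   # bright half
        out = clahe_normalize(img, tile_px=32, clip_limit=0.05)
        assert np.ptp(out[:, :64]) >= 0.5
        assert np.ptp(out[:, 64:]) >= 0.5

    def test_deterministic(self):
        img = np.random.default_rng(4).random((96, 96))
        np.testing.assert_array_equal(clahe_normalize(img), clahe_normalize(img))

    def test_bad_params_rejected(self):
        with pytest.raises(ValidationError):
            clahe_normalize(np.zeros((32, 32)), tile_px=4)
        with pytest.raises(ValidationError):
            clahe_normalize(np.zeros((32, 32)), clip_limit=0.0)


class TestBinarizeMarker:
    def test_fixed_threshold_checkerboard_exact(self):
        img = np.indices((16, 16)).sum(axis=0) % 2 * 0.2 + 0.4  # {0.4, 0.6}
        mask = binarize_marker(img, "fixed", threshold=0.5).mask
        np.testing.assert_array_equal(mask, img >= 0.5)

    def test_flat_otsu_empty_with_warning(self):
        with pytest.warns(UserWarning, match="flat"):
            mm = binarize_marker(np.ones((16, 16)), "otsu")
        assert not mm.mask.any() and mm.method.get("degenerate")

    def test_control_gate_without_gate_rejected(self):
        with pytest.raises(ValidationError, match="ControlGate"):
            binarize_marker(np.zeros((8, 8)), "control_gate")

    def test_control_gate_threshold_applied(self):
        gate = ControlGate(0.5, 99.0, 100)
        img = np.linspace(0, 1, 64).reshape(8, 8)
        mask = binarize_marker(img, "control_gate", gate=gate).mask
        np.testing.assert_array_equal(mask, img >= 0.5)

    def test_method_record_reproduces_mask(self):
        img = np.random.default_rng(5).random((32, 32))
        mm = binarize_marker(img, "otsu")
        np.testing.assert_array_equal(mm.mask, img >= mm.method["threshold"])

    def test_planted_coverages_recovered_with_fixed_threshold(
        self, ffpe_small_noiseless
    ):
        image, truth = ffpe_small_noiseless
        mm = binarize_marker(image.channel("trogo_marker"), "fixed", threshold=0.4)
        cells = CellMap(truth.territories, image.pixel_size_um)
        cov = coverage_fraction(cells, mm)
        assert np.abs(cov - truth.planted_coverage).max() <= 0.02


class TestControlThreshold:
    def test_constant_distribution_any_percentile(self):
        gate = control_threshold([3.0] * 50, 42.0)
        assert gate.intensity_threshold == 3.0
        assert gate.n_control_cells == 50

    def test_percentile_100_is_maximum(self):
        gate = control_threshold(np.arange(1, 101, dtype=float), 100.0)
        assert gate.intensity_threshold == 100.0

    def test_too_few_control_cells_rejected(self):
        with pytest.raises(ValidationError, match="control"):
            control_threshold([1.0] * 9, 99.0)

    def test_matches_analytic_lognormal_quantile(self):
        # per-cell autofluorescence amplitudes follow the generator's law:
        # base + LogNormal(ln(median), sigma)
        params = SyntheticParams()
        rng = np.random.default_rng(7)
        draws = params.af_base + rng.lognormal(
            np.log(params.af_median), params.af_sigma_log, size=20_000
        )
        gate = control_threshold(draws, 99.0)
        from scipy.stats import norm

        analytic = params.af_base + params.af_median * np.exp(
            params.af_sigma_log * norm.ppf(0.99)
        )
        assert abs(gate.intensity_threshold - analytic) / analytic <= 0.02


class TestPipelineDeterminism:
    def test_identical_input_identical_mask(self, ffpe_small_noiseless):
        image, _ = ffpe_small_noiseless
        ch = image.channel("trogo_marker")
        a = binarize_marker(clahe_normalize(subtract_background(ch, 10, PX)), "otsu")
        b = binarize_marker(clahe_normalize(subtract_background(ch, 10, PX)), "otsu")
        np.testing.assert_array_equal(a.mask, b.mask)
        assert a.method == b.method
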