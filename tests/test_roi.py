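"""Flat-region (sample inlet) extraction."""

import numpy as np
import pytest

import rgbelisa as rg


def solid(h, w, color):
    return np.tile(np.array(color, np.uint8), (h, w, 1))


class TestGrayscale:
    @pytest.mark.parametrize(
        "color, expected",
        [
            ((100, 100, 100), 100.0),  # equal channels: weights sum to 1
            ((255, 0, 0), 76.245),     # pure red: 0.299 * 255
            ((10, 20, 30), 18.15),     # BT.601 luma by hand
        ],
    )
    def test_luma_values(self, color, expected):
        gray = rg.to_grayscale(solid(4, 5, color))
        assert gray.shape == (4, 5)
        assert np.allclose(gray, expected)

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            rg.to_grayscale(np.zeros((0, 5, 3)))

    def test_custom_weights(self):
        gray = rg.to_grayscale(solid(2, 2, (10, 20, 30)), weights=(1.0, 0.0, 0.0))
        assert np.allclose(gray, 10.0)


class TestLaplacian:
    def test_constant_image_is_zero(self):
        assert np.all(rg.laplacian_gradient(np.full((9, 9), 37.0)) == 0.0)

    def test_interior_impulse_response(self):
        gray = np.zeros((9, 9))
        gray[4, 4] = 255.0
        grad = rg.laplacian_gradient(gray)
        assert grad[4, 4] == 8 * 255
        expected = np.full((3, 3), 255.0)
        expected[1, 1] = 8 * 255
        assert np.array_equal(grad[3:6, 3:6], expected)
        grad[3:6, 3:6] = 0.0
        assert np.all(grad == 0.0)

    def test_linear_ramp_annihilated_in_interior(self):
        gray = np.tile(np.arange(12, dtype=float), (8, 1))
        grad = rg.laplacian_gradient(gray)
        assert np.allclose(grad[1:-1, 1:-1], 0.0)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            rg.laplacian_gradient(np.zeros((2, 5)))


class TestScanWindows:
    @pytest.mark.parametrize(
        "shape, window, stride, expected_origins",
        [
            ((200, 200), 200, 10, [(0, 0)]),
            ((210, 210), 200, 10, [(0, 0), (0, 10), (10, 0), (10, 10)]),
            # stride misses the far edge: maximal origin appended (end clamp)
            ((205, 205), 200, 10, [(0, 0), (0, 5), (5, 0), (5, 5)]),
        ],
    )
    def test_origin_enumeration(self, shape, window, stride, expected_origins):
        grad = np.zeros(shape)
        wins = rg.scan_windows(grad, window, stride)
        assert [(r, c) for r, c, _ in wins] == expected_origins

    def test_window_statistic_is_mean(self):
        rng = np.random.default_rng(0)
        grad = rng.uniform(0, 10, (30, 40))
        wins = rg.scan_windows(grad, 20, 5)
        for r, c, stat in wins:
            assert stat == pytest.approx(grad[r : r + 20, c : c + 20].mean(), rel=1e-12)

    @pytest.mark.parametrize("h, w, window, stride", [
        (37, 53, 11, 3), (40, 40, 40, 7), (64, 30, 13, 13), (101, 77, 25, 10),
    ])
    def test_count_matches_closed_form(self, h, w, window, stride):
        def n_axis(extent):
            n = (extent - window) // stride + 1
            return n + (1 if (extent - window) % stride else 0)

        wins = rg.scan_windows(np.zeros((h, w)), window, stride)
        assert len(wins) == n_axis(h) * n_axis(w)

    def test_oversized_window_rejected(self):
        with pytest.raises(ValueError):
            rg.scan_windows(np.zeros((50, 50)), 60, 10)


class TestExtractRoi:
    def test_constant_image_first_window_wins(self):
        roi = rg.extract_roi(solid(220, 230, (50, 60, 70)), window=200, stride=10)
        assert (roi.origin_row, roi.origin_col) == (0, 0)
        assert np.all(roi.R == 50) and np.all(roi.G == 60) and np.all(roi.B == 70)

    def test_twin_flat_patches_row_major_tiebreak(self):
        # two identical flat patches, phase-aligned on the checkerboard so
        # their interior windows tie at exactly zero gradient
        rows = np.arange(80) // 4
        cols = np.arange(120) // 4
        tiles = ((rows[:, None] + cols[None, :]) % 2).astype(np.uint8)
        img = np.repeat((100 + 50 * tiles)[:, :, None], 3, axis=2)
        img[8:38, 8:38] = 100
        img[48:78, 48:78] = 100
        roi = rg.extract_roi(img, window=20, stride=2)
        # first fully-flat window in row-major order sits just inside patch 1
        assert (roi.origin_row, roi.origin_col) == (10, 10)
        assert roi.gradient_intensity == 0.0

    def test_planted_inlet_recovered(self):
        spec = rg.PhantomSpec(
            image_height=300, image_width=360, inlet_origin=(57, 93),
            inlet_size=140, noise_sd=0.0, seed=5,
        )
        img = rg.render_phantom(spec, 100.0)
        roi = rg.extract_roi(img, window=100, stride=10)
        assert 57 <= roi.origin_row and roi.origin_row + 100 <= 57 + 140
        assert 93 <= roi.origin_col and roi.origin_col + 100 <= 93 + 140

    def test_gradient_intensity_recomputes_exactly(self):
        rng = np.random.default_rng(2)
        img = rng.integers(0, 255, (120, 150, 3)).astype(np.uint8)
        roi = rg.extract_roi(img, window=50, stride=7)
        grad = rg.laplacian_gradient(rg.to_grayscale(img))
        assert roi.gradient_intensity == rg.window_gradient(
            grad, roi.origin_row, roi.origin_col, roi.size
        )

    def test_invariant_to_constant_offset(self):
        rng = np.random.default_rng(3)
        img = rng.integers(60, 180, (90, 110, 3)).astype(np.uint8)
        roi_a = rg.extract_roi(img, window=40, stride=5)
        roi_b = rg.extract_roi(img + np.uint8(20), window=40, stride=5)
        assert (roi_a.origin_row, roi_a.origin_col) == (roi_b.origin_row, roi_b.origin_col)
        assert roi_a.gradient_intensity == roi_b.gradient_intensity

    def test_report_roundtrip(self, tmp_path):
        import json

        roi = rg.extract_roi(solid(60, 60, (10, 20, 30)), window=40, stride=10)
        path = tmp_path / "roi.json"
        roi.save_report(path)
        report = json.loads(path.read_text())
        assert report["origin_row"] == 0 and report["size"] == 40
        assert report["mean_b"] == pytest.approx(30.0)
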