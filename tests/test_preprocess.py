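"""MAP projection, angular correction, normalization, tiling, splitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from biraster.core import AScanVolume, ScanGeometry
from biraster.preprocess import (
    angular_correction,
    angular_distort,
    crop_tiles,
    map_project,
    normalize,
    paste_tiles,
    split_dataset,
)


class TestMapProject:
    def test_single_voxel_lands_at_transposed_position(self):
        amp = np.zeros((3, 4, 5))
        amp[1, 2, 3] = 0.7
        img = map_project(AScanVolume(amp, (10, 4, 4)))
        assert img.shape == (5, 4)  # (n_lines, n_fast)
        assert img[3, 2] == 0.7
        assert img.sum() == pytest.approx(0.7)

    def test_constant_volume_projects_to_constant(self):
        img = map_project(AScanVolume(np.full((3, 4, 5), 0.3), (1, 1, 1)))
        np.testing.assert_allclose(img, 0.3)

    def test_matches_triple_loop_oracle(self, rng):
        amp = rng.random((4, 5, 6))
        img = map_project(AScanVolume(amp, (1, 1, 1)))
        for x in range(5):
            for y in range(6):
                expected = max(amp[z, x, y] for z in range(4))
                assert img[y, x] == pytest.approx(expected)


class TestAngularCorrection:
    def test_small_angle_limit_is_identity(self, rng):
        geo = ScanGeometry(n_fast=50, galvo_amplitude_deg=0.05)
        img = rng.random((4, 50))
        np.testing.assert_allclose(angular_correction(img, geo), img, atol=1e-6)

    def test_round_trip_recovers_smooth_line(self):
        geo = ScanGeometry(n_fast=200, galvo_amplitude_deg=15.0)
        x = np.linspace(0, 1, 200)
        line = (0.5 + 0.4 * np.sin(4 * np.pi * x))[None, :]
        distorted = angular_distort(line, geo)
        recovered = angular_correction(distorted, geo)
        np.testing.assert_allclose(recovered, line, atol=1e-3)

    def test_constant_line_unchanged(self):
        geo = ScanGeometry(n_fast=64, galvo_amplitude_deg=12.0)
        out = angular_correction(np.full((2, 64), 0.4), geo)
        np.testing.assert_allclose(out, 0.4)

    def test_width_mismatch_rejected(self):
        with pytest.raises(ValueError):
            angular_correction(np.zeros((3, 10)), ScanGeometry(n_fast=250))


class TestNormalize:
    def test_minmax_maps_extremes_to_unit_interval(self):
        np.testing.assert_allclose(
            normalize(np.array([[0.0, 5.0, 10.0]])), [[0.0, 0.5, 1.0]]
        )

    def test_constant_image_maps_to_zero(self):
        np.testing.assert_array_equal(normalize(np.full((4, 4), 3.0)), 0.0)

    def test_percentile_clips_hot_outlier(self, rng):
        img = rng.random((50, 50))
        img[10, 10] = 1e6
        out = normalize(img, mode="percentile")
        assert out[10, 10] == 1.0
        # remaining range matches a sort-based percentile computation
        lo, hi = np.percentile(img, [0.1, 99.9])
        inner = np.delete(img.ravel(), 10 * 50 + 10)
        expected = (np.clip(inner, lo, hi) - lo) / (hi - lo)
        np.testing.assert_allclose(np.delete(out.ravel(), 10 * 50 + 10), expected)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            normalize(np.array([[np.nan, 1.0]]))


class TestCropTiles:
    def test_single_tile_fits_250(self, rng):
        tiles = crop_tiles(rng.random((250, 250)), 192)
        assert len(tiles) == 1 and tiles[0][1] == (0, 0)

    def test_four_tiles_from_384(self, rng):
        assert len(crop_tiles(rng.random((384, 384)), 192)) == 4

    def test_paste_reproduces_covered_region(self, rng):
        img = rng.random((384, 384))
        tiles = crop_tiles(img, 192)
        np.testing.assert_array_equal(paste_tiles(tiles, img.shape), img)

    def test_undersized_image_rejected(self):
        with pytest.raises(ValueError):
            crop_tiles(np.zeros((100, 300)), 192)


class TestSplitDataset:
    def test_reproduces_published_counts(self):
        """1154 pairs at 8:2 then 9:1 -> 231 test, 93 validation, 830 train."""
        s = split_dataset(1154, 0.2, 0.1, seed=0)
        assert len(s.test) == 231
        assert len(s.validation) == 93
        assert len(s.train) == 830

    def test_ceiling_arithmetic_small_n(self):
        s = split_dataset(10, 0.2, 0.1, seed=1)
        assert (len(s.test), len(s.validation), len(s.train)) == (2, 1, 7)

    def test_deterministic_under_seed(self):
        assert split_dataset(57, seed=4) == split_dataset(57, seed=4)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(100, test_frac=1.5)

    @settings(deadline=None, max_examples=25)
    @given(n=st.integers(10, 400), seed=st.integers(0, 10))
    def test_partition_property(self, n, seed):
        s = split_dataset(n, seed=seed)
        all_idx = sorted(s.train + s.validation + s.test)
        assert all_idx == list(range(n))
        assert len(s.test) == -(-n * 2 // 10)
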