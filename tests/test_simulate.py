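"""Phantom scenes, scan trajectories and paired-acquisition properties."""

import numpy as np
import pytest
from dataclasses import replace

from biraster.core import InvalidGeometryError, InvalidJitterError, JitterModel, ScanGeometry
from biraster.metrics import ssim
from biraster.simulate import (
    generate_paired_dataset,
    line_trajectory,
    make_vessel_scene,
    render_scene,
    simulate_acquisition,
    theoretical_axial_resolution,
    theoretical_lateral_resolution,
)


class TestResolutionFormulas:
    def test_lateral_matches_system_value(self):
        # 0.51 * 532 nm / 0.032 = 8.5 um for the reference optics
        assert round(theoretical_lateral_resolution(0.032, 532), 1) == 8.5

    def test_lateral_formula_identity(self):
        assert theoretical_lateral_resolution(0.51, 510) == pytest.approx(0.51)

    def test_lateral_inverse_proportionality(self):
        assert theoretical_lateral_resolution(0.016, 532) == pytest.approx(
            2 * theoretical_lateral_resolution(0.032, 532)
        )

    def test_axial_matches_system_value(self):
        # 0.88 * 1540 / (20 MHz * 0.60) = 113 um
        assert round(theoretical_axial_resolution(20, 0.60, 1540)) == 113

    @pytest.mark.parametrize(
        "freq,bw", [(40, 0.60), (20, 1.20)], ids=["double-freq", "double-bw"]
    )
    def test_axial_inverse_scaling(self, freq, bw):
        assert theoretical_axial_resolution(freq, bw, 1540) == pytest.approx(
            theoretical_axial_resolution(20, 0.60, 1540) / 2
        )

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            theoretical_lateral_resolution(-0.1, 532)
        with pytest.raises(ValueError):
            theoretical_axial_resolution(20, 0.0)


class TestSceneGeneration:
    def test_deterministic_under_seed(self):
        s1 = make_vessel_scene(0, 5, (1.1, 1.0))
        s2 = make_vessel_scene(0, 5, (1.1, 1.0))
        assert len(s1.vessels) == len(s2.vessels)
        for v1, v2 in zip(s1.vessels, s2.vessels):
            np.testing.assert_array_equal(v1.points, v2.points)
            np.testing.assert_array_equal(v1.radii_um, v2.radii_um)

    def test_different_seeds_differ(self):
        s0 = make_vessel_scene(0, 5, (1.1, 1.0))
        s1 = make_vessel_scene(1, 5, (1.1, 1.0))
        assert not np.array_equal(s0.vessels[0].points, s1.vessels[0].points)

    @pytest.mark.parametrize("seed", [0, 3, 17])
    def test_vessel_density_within_bounds(self, seed):
        scene = make_vessel_scene(seed, 6, (0.6, 0.6))
        img = render_scene(scene, pixel_size_um=2.0)
        frac = np.mean(img > scene.background_level + 0.05)
        assert 0.01 <= frac <= 0.60

    def test_invalid_fov_rejected(self):
        with pytest.raises(InvalidGeometryError):
            make_vessel_scene(0, 3, (-1.0, 1.0))


class TestLineTrajectory:
    def test_zero_jitter_backward_is_reversed_forward(self, small_geometry):
        jit = JitterModel.zero()
        fwd = line_trajectory(small_geometry, jit, 1, "forward")
        bwd = line_trajectory(small_geometry, jit, 1, "backward")
        np.testing.assert_array_equal(bwd, fwd[::-1])

    def test_constant_lag_is_pure_shift(self, small_geometry):
        delta = 0.005
        jit = JitterModel(delta, 0.0, (), 0.0, 0)
        fwd = line_trajectory(small_geometry, jit, 1, "forward")
        bwd = line_trajectory(small_geometry, jit, 1, "backward")
        np.testing.assert_allclose(
            bwd, fwd[::-1] + delta * small_geometry.fov_x_mm, rtol=0, atol=1e-12
        )

    def test_same_seed_same_line_identical(self, small_geometry):
        jit = JitterModel(0.004, 0.002, (0.003,), 0.002, seed=9)
        a = line_trajectory(small_geometry, jit, 3, "backward")
        b = line_trajectory(small_geometry, jit, 3, "backward")
        np.testing.assert_array_equal(a, b)

    def test_monotonic_positions(self, small_geometry):
        jit = JitterModel(0.004, 0.002, (0.003,), 0.002, seed=4)
        for j in (1, 3, 5):
            pos = line_trajectory(small_geometry, jit, j, "backward")
            assert np.all(np.diff(pos) < 0)  # backward: strictly decreasing

    def test_foldover_rejected(self, small_geometry):
        # a distortion harmonic large enough to reverse the sweep locally
        jit = JitterModel(0.0, 0.0, (0.5,), 0.0, 0)
        with pytest.raises(InvalidJitterError):
            line_trajectory(small_geometry, jit, 1, "backward")

    def test_line_index_bounds(self, small_geometry):
        with pytest.raises(ValueError):
            line_trajectory(small_geometry, JitterModel.zero(), 10_000, "forward")


@pytest.fixture(scope="module")
def scene_and_ref():
    scene = make_vessel_scene(5, 4, (0.4, 0.4))
    return scene, render_scene(scene, 1.0)


class TestAcquisition:
    def test_zero_jitter_bidirectional_equals_unidirectional(self, scene_and_ref, small_geometry):
        scene, ref = scene_and_ref
        jit = JitterModel.zero()
        bi = simulate_acquisition(scene, small_geometry, jit, 0.0, reference=ref)
        uni = simulate_acquisition(
            scene,
            replace(small_geometry, mode="unidirectional", y_step_um=2.0),
            jit,
            0.0,
            reference=ref,
        )
        assert bi.shape == uni.shape
        np.testing.assert_allclose(bi, uni, atol=1e-9)

    def test_constant_lag_recovered_by_cross_correlation(self, scene_and_ref, small_geometry):
        scene, ref = scene_and_ref
        delta = 0.01  # fraction of span
        jit = JitterModel(delta, 0.0, (), 0.0, 0)
        img = simulate_acquisition(scene, small_geometry, jit, 0.0, reference=ref)
        clean = simulate_acquisition(scene, small_geometry, JitterModel.zero(), 0.0, reference=ref)
        expected_px = delta * small_geometry.n_fast
        shifts = np.arange(-5, 6)
        for j in range(1, small_geometry.n_lines, 8):  # backward lines
            row, ref_row = img[j], clean[j]
            cc = [
                np.corrcoef(np.roll(row, s)[5:-5], ref_row[5:-5])[0, 1] for s in shifts
            ]
            recovered = shifts[int(np.argmax(cc))]
            assert abs(recovered - expected_px) <= 1.0

    def test_doubling_y_step_halves_line_count(self, small_geometry):
        assert replace(small_geometry, y_step_um=8.0).n_lines == small_geometry.n_lines // 2

    def test_geometry_scene_fov_mismatch_rejected(self, scene_and_ref):
        scene, _ = scene_and_ref
        with pytest.raises(InvalidGeometryError):
            simulate_acquisition(scene, ScanGeometry(), JitterModel.zero())


class TestPairedDataset:
    def test_byte_identical_under_seed(self):
        kw = dict(n_pairs=3, seed=7, crop_size=64, crops_per_scene=3, ref_pixel_um=2.0)
        p1, m1 = generate_paired_dataset(**kw)
        p2, m2 = generate_paired_dataset(**kw)
        assert m1 == m2
        for a, b in zip(p1, p2):
            np.testing.assert_array_equal(a.input_img, b.input_img)
            np.testing.assert_array_equal(a.target_img, b.target_img)

    def test_zero_jitter_pairs_identical(self):
        pairs, _ = generate_paired_dataset(
            4,
            jitter=JitterModel.zero(),
            seed=3,
            crop_size=64,
            crops_per_scene=2,
            noise_sigma=0.0,
            ref_pixel_um=2.0,
        )
        for p in pairs:
            np.testing.assert_allclose(p.input_img, p.target_img, atol=1e-9)
            assert ssim(p.input_img, p.target_img) == pytest.approx(1.0, abs=1e-6)

    def test_default_jitter_degrades_similarity(self, scaled_dataset):
        pairs, _ = scaled_dataset
        mean_ssim = np.mean(
            [ssim(p.input_img, p.target_img) for p in pairs[:30]]
        )
        assert mean_ssim < 0.99

    def test_images_within_unit_range(self, scaled_dataset):
        pairs, _ = scaled_dataset
        for p in pairs[:10]:
            assert p.input_img.min() >= 0.0 and p.input_img.max() <= 1.0
            assert p.input_img.shape == (64, 64)

    def test_monotone_degradation_with_lag(self):
        """Mean SSIM is non-increasing as the mean phase lag grows."""
        means = []
        for lag in (0.0, 0.002, 0.005, 0.01):
            pairs, _ = generate_paired_dataset(
                8,
                jitter=JitterModel(lag, 0.0, (), 0.0, 0),
                seed=21,
                crop_size=64,
                crops_per_scene=4,
                noise_sigma=0.0,
                ref_pixel_um=2.0,
            )
            means.append(np.mean([ssim(p.input_img, p.target_img) for p in pairs]))
        assert all(a >= b - 2e-3 for a, b in zip(means, means[1:]))
        assert means[0] > means[-1]
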