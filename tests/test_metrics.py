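"""Metric suite: reference-oracle equivalence and qualitative properties."""

import numpy as np
import pytest
from scipy.ndimage import uniform_filter

from oracles import naive_ssim

from biraster.core import PairedSample
from biraster.metrics import (
    bad,
    baseline_filters,
    blur_score,
    evaluate_set,
    mae,
    ms_ssim,
    mse,
    psnr,
    ssim,
)


class TestSSIM:
    def test_self_similarity(self, rng):
        x = rng.random((32, 32))
        assert ssim(x, x) == pytest.approx(1.0)

    def test_inverted_checkerboard_anticorrelates(self):
        cb = (np.indices((32, 32)).sum(0) % 2).astype(float)
        assert ssim(cb, 1 - cb) < 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_window_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.random((32, 32)), rng.random((32, 32))
        assert ssim(a, b) == pytest.approx(naive_ssim(a, b), abs=1e-6)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            ssim(rng.random((8, 8)), rng.random((9, 8)))


class TestMSSSIM:
    def test_self_similarity(self, rng):
        x = rng.random((200, 200))
        assert ms_ssim(x, x) == pytest.approx(1.0)

    def test_exceeds_single_scale_for_high_frequency_noise(self, rng):
        base = uniform_filter(rng.random((200, 200)), 7)
        noisy = base + rng.normal(0, 0.03, base.shape)
        assert ms_ssim(base, noisy) >= ssim(base, noisy)

    def test_small_images_reduce_scales(self, rng):
        x = rng.random((40, 40))
        assert 0.0 <= ms_ssim(x, x) == pytest.approx(1.0)


class TestPSNR:
    def test_offset_closed_forms(self):
        a = np.zeros((16, 16))
        assert psnr(a, a + 0.1) == pytest.approx(20.0, abs=1e-9)
        assert psnr(a, a + 0.01) == pytest.approx(40.0, abs=1e-9)

    def test_symmetry_and_identity_sentinel(self, rng):
        a, b = rng.random((8, 8)), rng.random((8, 8))
        assert psnr(a, b) == pytest.approx(psnr(b, a))
        assert np.isinf(psnr(a, a))


class TestMAEMSE:
    def test_identical_images_zero(self, rng):
        x = rng.random((8, 8))
        assert mae(x, x) == 0.0 and mse(x, x) == 0.0

    def test_constant_offset(self):
        a = np.zeros((4, 4))
        assert mae(a, a + 0.25) == pytest.approx(0.25)
        assert mse(a, a + 0.25) == pytest.approx(0.0625)

    def test_matches_loop_oracle(self, rng):
        a, b = rng.random((3, 3)), rng.random((3, 3))
        expected_mae = sum(abs(a[i, j] - b[i, j]) for i in range(3) for j in range(3)) / 9
        expected_mse = sum((a[i, j] - b[i, j]) ** 2 for i in range(3) for j in range(3)) / 9
        assert mae(a, b) == pytest.approx(expected_mae)
        assert mse(a, b) == pytest.approx(expected_mse)


class TestBlurScore:
    def test_smoothing_increases_blurriness(self):
        cb = ((np.indices((64, 64)).sum(0) // 8) % 2).astype(float)
        assert blur_score(cb) < blur_score(uniform_filter(cb, 9))

    def test_transpose_symmetry(self, rng):
        img = rng.random((32, 48))
        assert blur_score(img) == pytest.approx(blur_score(img.T))

    def test_flat_image_scores_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert blur_score(np.full((32, 32), 0.5)) == 0.0

    def test_score_within_unit_interval(self, rng):
        assert 0.0 <= blur_score(rng.random((32, 32))) <= 1.0


class TestBAD:
    def test_identity_and_symmetry(self, rng):
        a, b = rng.random((32, 32)), rng.random((32, 32))
        assert bad(a, a) == 0.0
        assert bad(a, b) == pytest.approx(bad(b, a))

    def test_equals_blur_score_difference(self):
        sharp = ((np.indices((64, 64)).sum(0) // 8) % 2).astype(float)
        blurred = uniform_filter(sharp, 5)
        assert bad(sharp, blurred) == pytest.approx(
            abs(blur_score(sharp) - blur_score(blurred))
        )


class TestBaselineFilters:
    def test_median_preserves_constants(self):
        out = baseline_filters(np.full((16, 16), 0.5), "median")
        np.testing.assert_allclose(out, 0.5)

    def test_median_removes_impulse(self):
        img = np.zeros((16, 16))
        img[8, 8] = 1.0
        assert baseline_filters(img, "median", window=3)[8, 8] == 0.0

    @pytest.mark.parametrize("method", ["bicubic", "bilateral", "median"])
    def test_outputs_stay_in_unit_range(self, method, rng):
        out = baseline_filters(rng.random((32, 32)), method)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_unknown_method_rejected(self, rng):
        with pytest.raises(ValueError):
            baseline_filters(rng.random((16, 16)), "wavelet")


class TestEvaluateSet:
    def _pairs(self, rng, n=3, identical=False):
        out = []
        for _ in range(n):
            t = rng.random((32, 32)).astype(np.float32)
            x = t if identical else np.clip(t + rng.normal(0, 0.05, t.shape), 0, 1)
            out.append(PairedSample(x.astype(np.float32), t, np.zeros(4), 0))
        return out

    def test_identical_pairs_have_perfect_input_column(self, rng):
        report = evaluate_set(self._pairs(rng, identical=True))
        s = report.summary
        assert s.loc["SSIM", ("mean", "input")] == pytest.approx(1.0)
        assert s.loc["MAE", ("mean", "input")] == 0.0
        # PSNR is +inf for identical pairs and excluded from the mean
        assert np.isnan(s.loc["PSNR", ("mean", "input")])

    def test_single_pair_has_zero_sd(self, rng):
        report = evaluate_set(self._pairs(rng, n=1))
        assert (report.summary["sd"].fillna(0) == 0).all().all()

    def test_summary_matches_per_image_recomputation(self, rng):
        report = evaluate_set(self._pairs(rng, n=4))
        sub = report.per_image.query("method=='input' and metric=='SSIM'")["value"]
        assert report.summary.loc["SSIM", ("mean", "input")] == pytest.approx(sub.mean())
        assert report.summary.loc["SSIM", ("sd", "input")] == pytest.approx(sub.std(ddof=0))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            evaluate_set([])
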