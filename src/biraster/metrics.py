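"""Full-reference image-quality metrics and classical filter baselines.

The metric suite used to compare correction methods: SSIM, multiscale
SSIM, PSNR, MAE, MSE, and BAD — the *blur absolute difference*, i.e. the
absolute difference between the no-reference perceptual blur scores of two
images. The blur score follows the Crete-Roffet estimator: an image is
re-blurred with 9-tap averaging kernels and the fraction of neighbour
variation that survives re-blurring measures how blurred the image already
was (0 = sharp, 1 = fully blurred).

All metrics operate on same-shape grayscale images normalized to [0, 1].
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.metrics import structural_similarity
from skimage.restoration import denoise_bilateral
from skimage.transform import resize

__all__ = [
    "ssim",
    "ms_ssim",
    "psnr",
    "mae",
    "mse",
    "blur_score",
    "bad",
    "baseline_filters",
    "MetricReport",
    "evaluate_set",
    "METRIC_NAMES",
]

log = logging.getLogger(__name__)

METRIC_NAMES = ("SSIM", "MS-SSIM", "PSNR", "MAE", "MSE", "BAD")

# canonical 5-scale weights of multiscale SSIM
_MSSSIM_WEIGHTS = np.array([0.0448, 0.2856, 0.3001, 0.2363, 0.1333])


def _check_pair(a, b):
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("images must share one shape")
    return a, b


def ssim(a: np.ndarray, b: np.ndarray, data_range: float = 1.0) -> float:
    """Mean structural similarity, 11x11 Gaussian window (sigma 1.5).

    Uses the Wang et al. convention (Gaussian weights, population
    covariance, K1=0.01, K2=0.03); local values are averaged over the
    valid window region.
    """
    a, b = _check_pair(a, b)
    return float(
        structural_similarity(
            a,
            b,
            data_range=data_range,
            gaussian_weights=True,
            sigma=1.5,
            win_size=11,
            use_sample_covariance=False,
        )
    )


def _window_stats(a, b, data_range):
    """Valid-region luminance and contrast-structure SSIM components."""
    C1 = (0.01 * data_range) ** 2
    C2 = (0.03 * data_range) ** 2
    trunc = (11 - 1) / 2 / 1.5

    def blur(x):
        return ndimage.gaussian_filter(x, 1.5, truncate=trunc, mode="nearest")

    mx, my = blur(a), blur(b)
    sxx = blur(a * a) - mx**2
    syy = blur(b * b) - my**2
    sxy = blur(a * b) - mx * my
    lum = (2 * mx * my + C1) / (mx**2 + my**2 + C1)
    cs = (2 * sxy + C2) / (sxx + syy + C2)
    pad = 5
    if min(lum.shape) > 2 * pad:
        lum = lum[pad:-pad, pad:-pad]
        cs = cs[pad:-pad, pad:-pad]
    return float(lum.mean()), float(cs.mean())


def ms_ssim(a: np.ndarray, b: np.ndarray, data_range: float = 1.0) -> float:
    """Multiscale SSIM with the canonical 5-scale weights.

    Contrast-structure terms are accumulated at every scale and the
    luminance term enters at the coarsest scale only; downsampling is 2x2
    average pooling. For images too small for five scales the scale count
    is reduced and the weights renormalized.
    """
    a, b = _check_pair(a, b)
    n_scales = 5
    # each scale needs at least the 11-pixel window after s-1 halvings
    while n_scales > 1 and min(a.shape) // 2 ** (n_scales - 1) < 11:
        n_scales -= 1
    weights = _MSSSIM_WEIGHTS[:n_scales]
    weights = weights / weights.sum()
    vals = []
    for s in range(n_scales):
        lum, cs = _window_stats(a, b, data_range)
        vals.append(lum if s == n_scales - 1 else cs)
        if s < n_scales - 1:
            h, w = (a.shape[0] // 2) * 2, (a.shape[1] // 2) * 2
            a = a[:h, :w].reshape(h // 2, 2, w // 2, 2).mean(axis=(1, 3))
            b = b[:h, :w].reshape(h // 2, 2, w // 2, 2).mean(axis=(1, 3))
    # negative components are clamped so the weighted geometric mean is real
    vals = np.maximum(vals, 0.0)
    lum_term = vals[-1] ** weights[-1]
    cs_terms = np.prod(vals[:-1] ** weights[:-1]) if n_scales > 1 else 1.0
    return float(lum_term * cs_terms)


def psnr(a: np.ndarray, b: np.ndarray, max_val: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical images."""
    a, b = _check_pair(a, b)
    err = float(np.mean((a - b) ** 2))
    if err == 0.0:
        return float("inf")
    return float(10.0 * np.log10(max_val**2 / err))


def mae(a: np.ndarray, b: np.ndarray) -> float:
    a, b = _check_pair(a, b)
    return float(np.mean(np.abs(a - b)))


def mse(a: np.ndarray, b: np.ndarray) -> float:
    a, b = _check_pair(a, b)
    return float(np.mean((a - b) ** 2))


def blur_score(image: np.ndarray) -> float:
    """No-reference perceptual blur in [0, 1] (0 = sharp, 1 = blurred).

    Crete-Roffet estimator: re-blur the image with 1x9 and 9x1 averaging
    kernels; along each axis, compare the total absolute neighbour
    variation of the original with the variation destroyed by re-blurring.
    An already-blurred image loses almost nothing, a sharp one loses most.
    The final score is the worse (blurrier) of the two axes.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2 or min(img.shape) < 16:
        raise ValueError("need a 2D image with min side >= 16")
    kernel = np.ones(9) / 9.0
    scores = []
    for axis in (0, 1):
        blurred = ndimage.correlate1d(img, kernel, axis=axis, mode="nearest")
        d_orig = np.abs(np.diff(img, axis=axis))
        d_blur = np.abs(np.diff(blurred, axis=axis))
        lost = np.maximum(0.0, d_orig - d_blur)
        s_orig = d_orig.sum()
        if s_orig == 0.0:
            scores.append(0.0)
            continue
        scores.append(float((s_orig - lost.sum()) / s_orig))
    if all(s == 0.0 for s in scores) and np.ptp(img) == 0.0:
        warnings.warn("flat image has no variation; blur score set to 0")
        return 0.0
    return float(np.clip(max(scores), 0.0, 1.0))


def bad(a: np.ndarray, b: np.ndarray) -> float:
    """Blur absolute difference: |blur(a) - blur(b)|."""
    a, b = _check_pair(a, b)
    return abs(blur_score(a) - blur_score(b))


def baseline_filters(
    image: np.ndarray,
    method: str,
    window: int = 5,
    sigma_color: float = 0.1,
    sigma_spatial: float = 2.0,
) -> np.ndarray:
    """Classical enhancement baselines the network is compared against.

    ``bicubic`` halves then re-doubles the image bicubically (the
    upsampling baseline); ``bilateral`` and ``median`` are edge-preserving
    and rank filters with the given windows.
    """
    img = np.asarray(image, dtype=np.float64)
    if method == "bicubic":
        h, w = img.shape
        small = resize(img, (h // 2, w // 2), order=3, anti_aliasing=True)
        out = resize(small, (h, w), order=3)
    elif method == "bilateral":
        out = denoise_bilateral(
            np.clip(img, 0, 1),
            win_size=window,
            sigma_color=sigma_color,
            sigma_spatial=sigma_spatial,
        )
    elif method == "median":
        out = ndimage.median_filter(img, size=window)
    else:
        raise ValueError(f"unknown baseline method {method!r}")
    return np.clip(out, 0.0, 1.0)


@dataclass
class MetricReport:
    """Per-image metric values and mean +/- SD per method column."""

    per_image: pd.DataFrame  # columns: method, pair, metric, value
    summary: pd.DataFrame  # index: metric; columns: <method> mean / sd

    def to_csv(self, path) -> None:
        self.summary.to_csv(path)


def _all_metrics(a, b):
    return {
        "SSIM": ssim(a, b),
        "MS-SSIM": ms_ssim(a, b),
        "PSNR": psnr(a, b),
        "MAE": mae(a, b),
        "MSE": mse(a, b),
        "BAD": bad(a, b),
    }


def evaluate_set(pairs, methods: dict | None = None) -> MetricReport:
    """Evaluate correction methods over a set of paired samples.

    ``methods`` maps column name to a callable ``image -> image`` applied
    to each pair's input; the raw input passthrough column is always
    included. Non-finite PSNR values (identical images) are excluded from
    the mean with a logged count.
    """
    if len(pairs) == 0:
        raise ValueError("need at least one pair")
    methods = {"input": lambda im: im, **(methods or {})}
    rows = []
    for name, fn in methods.items():
        for i, pair in enumerate(pairs):
            out = np.asarray(fn(np.asarray(pair.input_img)), dtype=np.float64)
            for metric, value in _all_metrics(out, np.asarray(pair.target_img)).items():
                rows.append(
                    {"method": name, "pair": i, "metric": metric, "value": value}
                )
    per_image = pd.DataFrame(rows)
    n_inf = int((~np.isfinite(per_image["value"])).sum())
    if n_inf:
        log.info("excluding %d non-finite metric values from summary means", n_inf)
    finite = per_image[np.isfinite(per_image["value"])]
    g = finite.groupby(["metric", "method"])["value"]
    summary = pd.concat(
        {"mean": g.mean(), "sd": g.std(ddof=0)}, axis=1
    ).unstack("method")
    summary = summary.reindex(list(METRIC_NAMES))
    return MetricReport(per_image, summary)
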