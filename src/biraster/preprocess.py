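"""Raw-acquisition preprocessing: MAP projection, angular correction,
normalization, tiling, and dataset splitting.

The angular correction undoes the deterministic part of the galvanometer
distortion: a mirror swept at constant angular rate samples positions
``x(theta) = (L/2) * sin(theta) / sin(theta_max)`` rather than a uniform
grid, compressing pixels near the line ends. Resampling each line from
those sinusoidal positions onto the uniform grid removes this known
warping; the stochastic per-line timing jitter is deliberately left in
place for the network to correct.
"""

from __future__ import annotations

import math

import numpy as np

from .core import AScanVolume, ScanGeometry, SplitIndices

__all__ = [
    "map_project",
    "angular_positions",
    "angular_correction",
    "angular_distort",
    "normalize",
    "crop_tiles",
    "paste_tiles",
    "split_dataset",
]


def map_project(volume: AScanVolume) -> np.ndarray:
    """Maximum amplitude projection along depth -> (n_lines, n_fast) image."""
    amp = volume.amplitudes
    if amp.shape[0] < 1 or amp.size == 0:
        raise ValueError("cannot project an empty volume")
    return np.ascontiguousarray(amp.max(axis=0).T)


def angular_positions(n_fast: int, fov_x_mm: float, theta_max_rad: float) -> np.ndarray:
    """Physical sample positions (mm) of a sinusoidal galvo sweep.

    Mirror angles are uniform in [-theta_max, theta_max]; positions follow
    (L/2)*sin(theta)/sin(theta_max), shifted so the line spans [0, L].
    """
    theta = np.linspace(-theta_max_rad, theta_max_rad, n_fast)
    half = fov_x_mm / 2.0
    return half * np.sin(theta) / math.sin(theta_max_rad) + half


def angular_correction(image: np.ndarray, geometry: ScanGeometry) -> np.ndarray:
    """Resample each line from sinusoidal galvo positions onto a uniform grid."""
    img = np.asarray(image, dtype=np.float64)
    if img.shape[-1] != geometry.n_fast:
        raise ValueError(
            f"line length {img.shape[-1]} does not match geometry n_fast {geometry.n_fast}"
        )
    theta_max = math.radians(geometry.galvo_amplitude_deg)
    if theta_max <= 1e-3:  # small-angle limit: sampling already uniform
        return img.copy()
    src = angular_positions(geometry.n_fast, geometry.fov_x_mm, theta_max)
    dst = np.linspace(0.0, geometry.fov_x_mm, geometry.n_fast)
    out = np.empty_like(img)
    for i in range(img.shape[0]):
        out[i] = np.interp(dst, src, img[i])
    return out


def angular_distort(image: np.ndarray, geometry: ScanGeometry) -> np.ndarray:
    """Forward model of the galvo distortion (inverse of the correction).

    Takes a uniformly sampled line and produces what the sinusoidal sweep
    would have recorded; useful for round-trip validation.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.shape[-1] != geometry.n_fast:
        raise ValueError("line length does not match geometry")
    theta_max = math.radians(geometry.galvo_amplitude_deg)
    if theta_max <= 1e-3:
        return img.copy()
    src = np.linspace(0.0, geometry.fov_x_mm, geometry.n_fast)
    dst = angular_positions(geometry.n_fast, geometry.fov_x_mm, theta_max)
    out = np.empty_like(img)
    for i in range(img.shape[0]):
        out[i] = np.interp(dst, src, img[i])
    return out


def normalize(
    image: np.ndarray,
    mode: str = "minmax",
    p_low: float = 0.1,
    p_high: float = 99.9,
) -> np.ndarray:
    """Map an image into [0, 1]; constant images map to zero.

    ``percentile`` mode clips at the (p_low, p_high) percentiles before the
    min-max mapping, which protects against isolated hot pixels.
    """
    img = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    if mode == "percentile":
        lo, hi = np.percentile(img, [p_low, p_high])
        img = np.clip(img, lo, hi)
    elif mode != "minmax":
        raise ValueError(f"unknown normalization mode {mode!r}")
    lo, hi = img.min(), img.max()
    if hi <= lo:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def crop_tiles(image: np.ndarray, size: int = 192, stride: int | None = None):
    """Cut an image into size x size tiles on a regular grid.

    Tiles start at the top-left corner and advance by ``stride`` (default:
    non-overlapping); any remainder that cannot fit a full tile is
    discarded. Returns a list of ``(tile, (row_offset, col_offset))``.
    """
    img = np.asarray(image)
    if img.shape[0] < size or img.shape[1] < size:
        raise ValueError("image smaller than the requested tile size")
    stride = stride or size
    tiles = []
    for r in range(0, img.shape[0] - size + 1, stride):
        for c in range(0, img.shape[1] - size + 1, stride):
            tiles.append((img[r : r + size, c : c + size].copy(), (r, c)))
    return tiles

def paste_tiles(tiles, shape) -> np.ndarray:
    """Reassemble tiles at their offsets (later tiles overwrite overlaps)."""
    out = np.zeros(shape, dtype=np.asarray(tiles[0][0]).dtype)
    for tile, (r, c) in tiles:
        out[r : r + tile.shape[0], c : c + tile.shape[1]] = tile
    return out


def split_dataset(
    n: int, test_frac: float = 0.2, val_frac: float = 0.1, seed: int = 0
) -> SplitIndices:
    """Random train/validation/test split with ceiling-sized held-out sets.

    The test set takes ``ceil(test_frac * n)`` samples; the validation set
    ``ceil(val_frac * (n - n_test))`` of the remainder; everything else
    trains. For 1154 samples at the 8:2 then 9:1 ratios this yields
    231 test / 93 validation / 830 training samples.
    """
    if n < 10:
        raise ValueError("need at least 10 samples to split")
    for f in (test_frac, val_frac):
        if not (0.0 < f < 1.0):
            raise ValueError("split fractions must lie in (0, 1)")
    n_test = math.ceil(test_frac * n)
    n_val = math.ceil(val_frac * (n - n_test))
    perm = np.random.default_rng(seed).permutation(n)
    return SplitIndices(
        train=tuple(int(i) for i in perm[n_test + n_val :]),
        validation=tuple(int(i) for i in perm[n_test : n_test + n_val]),
        test=tuple(int(i) for i in perm[:n_test]),
    )
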