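"""Slice-wise 3D correction and volumetric rendering.

A generator trained on 2D en-face images extends to volumes by correcting
each fixed-depth (x, y) plane independently and reassembling the stack.
Each plane is min-max normalized before inference and the normalization is
inverted afterwards, so dim deep planes keep their global amplitude
relation to bright superficial ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib
import numpy as np

from .core import AScanVolume
from .preprocess import map_project
from .training import infer

__all__ = ["DepthEncodedImage", "correct_volume", "depth_encode", "stitch_segments"]

# planes with less amplitude range than this are passed through unchanged
# (normalizing near-empty planes would only amplify noise)
MIN_PLANE_RANGE = 1e-6


@dataclass
class DepthEncodedImage:
    """2D RGB rendering: hue encodes depth-of-maximum, brightness amplitude."""

    rgb: np.ndarray
    colormap: str
    depth_range_mm: tuple
    depth_of_max: np.ndarray  # depth indices, shape (n_lines, n_fast)


def correct_volume(volume: AScanVolume, generator) -> AScanVolume:
    """Apply the 2D correction network to every en-face plane of a volume.

    Planes are (x, y) slices at fixed z; each is transposed to the image
    convention (rows = slow axis), reflect-padded to the network's scale
    multiple, corrected, unpadded and de-normalized back into place.
    """
    amp = volume.amplitudes
    if amp.size == 0:
        raise ValueError("empty volume")
    out = np.empty_like(amp, dtype=np.float32)
    for z in range(amp.shape[0]):
        plane = amp[z].T.astype(np.float32)  # (n_lines, n_fast) image
        lo, hi = float(plane.min()), float(plane.max())
        if hi - lo < MIN_PLANE_RANGE:
            out[z] = amp[z]
            continue
        norm = (plane - lo) / (hi - lo)
        corrected = infer(generator, norm)
        out[z] = (corrected * (hi - lo) + lo).T
    return AScanVolume(out, volume.spacing_um, mode="corrected")


def depth_encode(volume: AScanVolume, colormap: str = "viridis") -> DepthEncodedImage:
    """Render a volume as a depth-encoded 2D image.

    Per (x, y) position the depth index of the maximum amplitude selects the
    hue (ties break toward the shallowest depth, numpy argmax convention)
    and the projected amplitude scales the brightness.
    """
    amp = volume.amplitudes
    nz = amp.shape[0]
    if nz < 2:
        raise ValueError("depth encoding needs at least two depth samples")
    zmax = amp.argmax(axis=0).T  # (n_lines, n_fast)
    mapimg = map_project(volume)
    rng = mapimg.max()
    brightness = mapimg / rng if rng > 0 else mapimg
    hue_frac = zmax.astype(np.float64) / (nz - 1)
    rgb = matplotlib.colormaps[colormap](hue_frac)[..., :3]
    rgb = rgb * brightness[..., None]
    depth_range = (0.0, (nz - 1) * volume.spacing_um[0] / 1000.0)
    return DepthEncodedImage(rgb.astype(np.float32), colormap, depth_range, zmax)


def stitch_segments(segments) -> np.ndarray:
    """Mosaic overlapping image segments with linear feathering.

    ``segments`` is a list of ``(image, (row_offset, col_offset))`` with
    non-negative offsets. In overlap regions each segment is weighted by
    its distance to its own border (a linear feather), so seams blend
    smoothly; uncovered canvas pixels are zero-filled and counted in a
    warning.
    """
    if not segments:
        raise ValueError("no segments to stitch")
    h = max(off[0] + np.asarray(img).shape[0] for img, off in segments)
    w = max(off[1] + np.asarray(img).shape[1] for img, off in segments)
    acc = np.zeros((h, w), dtype=np.float64)
    wacc = np.zeros((h, w), dtype=np.float64)
    for img, (r, c) in segments:
        img = np.asarray(img, dtype=np.float64)
        if r < 0 or c < 0:
            raise ValueError("segment offsets must be non-negative")
        hh, ww = img.shape
        ramp_r = np.minimum(np.arange(hh) + 1, np.arange(hh)[::-1] + 1)
        ramp_c = np.minimum(np.arange(ww) + 1, np.arange(ww)[::-1] + 1)
        weight = np.minimum.outer(ramp_r, ramp_c).astype(np.float64)
        acc[r : r + hh, c : c + ww] += img * weight
        wacc[r : r + hh, c : c + ww] += weight
    covered = wacc > 0
    out = np.zeros((h, w), dtype=np.float64)
    out[covered] = acc[covered] / wacc[covered]
    n_gap = int((~covered).sum())
    if n_gap:
        import warnings

        warnings.warn(f"{n_gap} mosaic pixels not covered by any segment")
    return out
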