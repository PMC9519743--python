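"""Shared domain types for bidirectional raster-scan simulation and correction.

Conventions
-----------
Images are row-major 2D float arrays in [0, 1]: rows index the slow axis
(y, one row per B-scan line), columns the fast axis (x). 3D photoacoustic
volumes are stored depth-first, ``(n_depth, n_fast, n_lines)``, so an
en-face plane at fixed depth is ``amplitudes[z]`` with axes (x, y).
Physical coordinates are millimetres; step sizes and resolutions are
micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "Vessel",
    "VesselScene",
    "ScanGeometry",
    "JitterModel",
    "PairedSample",
    "AScanVolume",
    "SplitIndices",
    "InvalidGeometryError",
    "InvalidJitterError",
]


class InvalidGeometryError(ValueError):
    """Raised when a scan geometry or scene geometry is inconsistent."""


class InvalidJitterError(ValueError):
    """Raised when a jitter realization folds the scan trajectory over itself."""


@dataclass(frozen=True)
class Vessel:
    """A single smooth vessel: control points with per-point radius.

    ``points`` is an (n, 2) array of (x, y) positions in mm; ``radii_um``
    holds the local half-width (Gaussian cross-section scale) at each control
    point; ``amplitude`` is the peak normalized photoacoustic amplitude and
    ``depth_frac`` the fractional depth of the vessel axis inside the
    imaging depth range (used only by the 3D acquisition path).
    """

    points: np.ndarray
    radii_um: np.ndarray
    amplitude: float
    depth_frac: float = 0.5

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        radii = np.asarray(self.radii_um, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise InvalidGeometryError("vessel needs >=2 control points of (x, y)")
        if radii.shape[0] != pts.shape[0]:
            raise InvalidGeometryError("one radius per control point required")
        if np.any(radii <= 0):
            raise InvalidGeometryError("vessel radii must be positive")
        if not (0.0 <= self.amplitude <= 1.0):
            raise InvalidGeometryError("vessel amplitude must lie in [0, 1]")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "radii_um", radii)


@dataclass(frozen=True)
class VesselScene:
    """A synthetic vascular scene standing in for in-vivo microvasculature."""

    vessels: tuple
    fov: tuple  # (x_mm, y_mm)
    background_level: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        fx, fy = self.fov
        if fx <= 0 or fy <= 0:
            raise InvalidGeometryError("field of view must be positive")
        if not (0.0 <= self.background_level <= 1.0):
            raise InvalidGeometryError("background level must lie in [0, 1]")
        pad_mm = max(float(v.radii_um.max()) for v in self.vessels) / 1000.0
        for v in self.vessels:
            if (
                np.any(v.points[:, 0] < -pad_mm)
                or np.any(v.points[:, 0] > fx + pad_mm)
                or np.any(v.points[:, 1] < -pad_mm)
                or np.any(v.points[:, 1] > fy + pad_mm)
            ):
                raise InvalidGeometryError(
                    "vessel control points exceed field of view by more than "
                    "one maximum radius"
                )


@dataclass(frozen=True)
class ScanGeometry:
    """Raster-scan geometry of one acquisition.

    The fast axis (x) is swept by the galvanometer with ``n_fast`` samples
    per line; the slow axis (y) advances ``y_step_um`` per line. In
    unidirectional mode both sweep directions are simulated but only forward
    lines are retained (halving the effective B-scan rate); in bidirectional
    mode forward and backward lines alternate.
    """

    fov_x_mm: float = 1.1
    fov_y_mm: float = 1.0
    n_fast: int = 250
    y_step_um: float = 4.0
    mode: Literal["unidirectional", "bidirectional"] = "bidirectional"
    galvo_amplitude_deg: float = 10.0
    psf_lateral_fwhm_um: float = 8.5
    psf_axial_fwhm_um: float = 113.0
    n_depth: int = 0
    z_step_um: float = 10.0

    def __post_init__(self) -> None:
        if self.fov_x_mm <= 0 or self.fov_y_mm <= 0:
            raise InvalidGeometryError("field of view must be positive")
        if self.n_fast < 2:
            raise InvalidGeometryError("n_fast must be >= 2")
        if self.y_step_um <= 0:
            raise InvalidGeometryError("y step must be positive")
        if self.mode not in ("unidirectional", "bidirectional"):
            raise InvalidGeometryError(f"unknown scan mode {self.mode!r}")

    @property
    def n_lines(self) -> int:
        """Number of acquired lines spanning the slow axis."""
        return int(round(self.fov_y_mm * 1000.0 / self.y_step_um))

    @property
    def fast_pitch_um(self) -> float:
        return self.fov_x_mm * 1000.0 / self.n_fast

    def with_y_step(self, y_step_um: float, mode: str | None = None) -> "ScanGeometry":
        return replace(self, y_step_um=y_step_um, mode=mode or self.mode)


@dataclass(frozen=True)
class JitterModel:
    """Stochastic model of non-uniform per-line scan timing.

    Backward-line coordinates are the reversed nominal grid shifted by a
    per-line lag (in fractions of the fast-axis span) and warped by a smooth
    odd-harmonic distortion; see :func:`biraster.simulate.line_trajectory`.
    With all fields zero the forward and backward trajectories coincide
    exactly.
    """

    phase_lag_mean: float = 0.004
    phase_lag_sd: float = 0.002
    distortion_coeffs: tuple = (0.003,)
    drift_amplitude: float = 0.002
    seed: int = 0

    @classmethod
    def zero(cls, seed: int = 0) -> "JitterModel":
        """A jitter model that leaves trajectories perfectly aligned."""
        return cls(0.0, 0.0, (), 0.0, seed)

    @property
    def is_zero(self) -> bool:
        return (
            self.phase_lag_mean == 0.0
            and self.phase_lag_sd == 0.0
            and self.drift_amplitude == 0.0
            and all(c == 0.0 for c in self.distortion_coeffs)
        )


@dataclass
class PairedSample:
    """One (bidirectional input, unidirectional target) training pair."""

    input_img: np.ndarray
    target_img: np.ndarray
    jitter_record: np.ndarray  # realized per-line lags (fraction of span)
    scene_seed: int
    crop_offset: tuple = (0, 0)

    def __post_init__(self) -> None:
        if self.input_img.shape != self.target_img.shape:
            raise ValueError("paired images must share one spatial grid")


@dataclass
class AScanVolume:
    """A 3D photoacoustic amplitude volume, depth-first ``(z, x, y)``."""

    amplitudes: np.ndarray
    spacing_um: tuple  # (z, x, y) micrometres per sample
    mode: str = "bidirectional"

    def __post_init__(self) -> None:
        amp = np.asarray(self.amplitudes)
        if amp.ndim != 3 or amp.size == 0:
            raise ValueError("volume must be a non-empty 3D array")
        if len(self.spacing_um) != 3 or any(s <= 0 for s in self.spacing_um):
            raise ValueError("three positive axis spacings required")
        self.amplitudes = amp

    @property
    def shape(self) -> tuple:
        return self.amplitudes.shape


@dataclass(frozen=True)
class SplitIndices:
    """Disjoint train / validation / test index partition of a dataset."""

    train: tuple
    validation: tuple
    test: tuple

    def __post_init__(self) -> None:
        all_idx = set(self.train) | set(self.validation) | set(self.test)
        n = len(self.train) + len(self.validation) + len(self.test)
        if len(all_idx) != n:
            raise ValueError("split indices must be disjoint")
        if all_idx != set(range(n)):
            raise ValueError("split indices must partition 0..n-1")
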