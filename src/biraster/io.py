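"""Readers and writers for images, volumes and paired datasets.

Amplitude images in [0, 1] are stored as 16-bit grayscale TIFF/PNG with the
quantization scale recorded, so a float round trip is exact to the 16-bit
step. Volumes travel as HDF5 (with axis spacings as attributes) or as TIFF
stacks with a JSON metadata description. Paired datasets use one HDF5 file
(groups ``/pairs/<idx>/input|target`` plus metadata) or a directory of
paired TIFFs with a JSON manifest; both dialects load identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .core import AScanVolume, PairedSample

__all__ = [
    "read_image",
    "write_image",
    "read_volume",
    "write_volume",
    "save_pairs_hdf5",
    "load_pairs_hdf5",
    "save_pairs_tiff",
    "load_pairs_tiff",
    "load_pairs",
]

_SCALE = 65535.0


def write_image(path, image: np.ndarray) -> None:
    """Write a grayscale image as 16-bit TIFF or PNG.

    Float images are assumed normalized to [0, 1] and are quantized to
    16 bits with the scale recorded (TIFF description / PNG is implicit);
    integer images are stored as-is.
    """
    path = Path(path)
    img = np.asarray(image)
    if np.issubdtype(img.dtype, np.floating):
        arr = np.round(np.clip(img, 0.0, 1.0) * _SCALE).astype(np.uint16)
        scaled = True
    elif img.dtype in (np.uint8, np.uint16):
        arr = img
        scaled = False
    else:
        raise ValueError(f"unsupported image dtype {img.dtype}")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(
            path, arr, description=json.dumps({"scale": _SCALE if scaled else None})
        )
    elif suffix == ".png":
        import imageio.v3 as iio

        iio.imwrite(path, arr)
    else:
        raise ValueError(f"unsupported image format {suffix!r}")


def read_image(path, as_float: bool | None = None) -> np.ndarray:
    """Read a TIFF/PNG image; scaled 16-bit data returns as float in [0, 1]."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            arr = tf.asarray()
            desc = tf.pages[0].description
        scale = None
        if desc:
            try:
                scale = json.loads(desc).get("scale")
            except (json.JSONDecodeError, AttributeError):
                scale = None
        if scale and as_float is not False:
            return arr.astype(np.float32) / scale
        return arr
    if suffix == ".png":
        import imageio.v3 as iio

        arr = iio.imread(path)
        if as_float:
            return arr.astype(np.float32) / _SCALE
        return arr
    raise ValueError(f"unsupported image format {suffix!r}")


def write_volume(path, volume: AScanVolume) -> None:
    """Write a volume as HDF5 (.h5/.hdf5) or a TIFF stack (.tif/.tiff)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("amplitudes", data=volume.amplitudes)
            ds.attrs["spacing_um"] = list(volume.spacing_um)
            ds.attrs["mode"] = volume.mode
            ds.attrs["axes"] = "zxy"
    elif suffix in (".tif", ".tiff"):
        meta = {"spacing_um": list(volume.spacing_um), "mode": volume.mode, "axes": "zxy"}
        tifffile.imwrite(
            path,
            volume.amplitudes.astype(np.float32),
            photometric="minisblack",
            description=json.dumps(meta),
        )
    else:
        raise ValueError(f"unsupported volume format {suffix!r}")


def read_volume(path) -> AScanVolume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            ds = f["amplitudes"]
            if "spacing_um" not in ds.attrs:
                raise KeyError("volume metadata missing key 'spacing_um'")
            return AScanVolume(
                ds[...],
                tuple(float(s) for s in ds.attrs["spacing_um"]),
                mode=str(ds.attrs.get("mode", "unknown")),
            )
    if suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            arr = tf.asarray()
            desc = tf.pages[0].description
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            raise KeyError("volume metadata missing key 'spacing_um'")
        if "spacing_um" not in meta:
            raise KeyError("volume metadata missing key 'spacing_um'")
        return AScanVolume(arr, tuple(meta["spacing_um"]), mode=meta.get("mode", "unknown"))
    raise ValueError(f"unsupported volume format {suffix!r}")


# ---------------------------------------------------------------------------
# Paired datasets
# ---------------------------------------------------------------------------


def save_pairs_hdf5(path, pairs, manifest: dict) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["manifest"] = json.dumps(manifest)
        grp = f.create_group("pairs")
        for i, p in enumerate(pairs):
            g = grp.create_group(str(i))
            g.create_dataset("input", data=p.input_img)
            g.create_dataset("target", data=p.target_img)
            g.create_dataset("lags", data=p.jitter_record)
            g.attrs["scene_seed"] = p.scene_seed
            g.attrs["crop_offset"] = list(p.crop_offset)


def load_pairs_hdf5(path):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"dataset not found: {path}")
    pairs = []
    with h5py.File(path, "r") as f:
        manifest = json.loads(f.attrs["manifest"])
        grp = f["pairs"]
        for key in sorted(grp, key=int):
            g = grp[key]
            pairs.append(
                PairedSample(
                    g["input"][...],
                    g["target"][...],
                    g["lags"][...],
                    int(g.attrs["scene_seed"]),
                    tuple(int(v) for v in g.attrs["crop_offset"]),
                )
            )
    return pairs, manifest


def save_pairs_tiff(directory, pairs, manifest: dict) -> None:
    """Paired 16-bit TIFF dialect: pair_NNNN_{input,target}.tif + manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, p in enumerate(pairs):
        write_image(directory / f"pair_{i:04d}_input.tif", p.input_img)
        write_image(directory / f"pair_{i:04d}_target.tif", p.target_img)
    with open(directory / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=1)


def load_pairs_tiff(directory):
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found in {directory}")
    with open(manifest_path) as f:
        manifest = json.load(f)
    pairs = []
    for i, rec in enumerate(manifest["pairs"]):
        pairs.append(
            PairedSample(
                read_image(directory / f"pair_{i:04d}_input.tif"),
                read_image(directory / f"pair_{i:04d}_target.tif"),
                np.asarray(rec["lags"]),
                int(rec["scene_seed"]),
                tuple(rec["crop"]),
            )
        )
    return pairs, manifest


def load_pairs(path):
    """Load either dataset dialect by inspecting the path."""
    path = Path(path)
    if path.is_dir():
        return load_pairs_tiff(path)
    return load_pairs_hdf5(path)
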