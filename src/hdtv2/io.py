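"""Reading and writing images, masks and measurements.

Grayscale PNG/TIFF images (8- or 16-bit) are linearly mapped to [0, 1] on
load; saving defaults to 16-bit to keep round-trip quantization below 1/65535.
Exact arrays (masks, complex measurements, float images) round-trip through
NPY files losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .linops import FourierMask, Measurement

__all__ = [
    "load_image",
    "save_image",
    "save_mask",
    "load_mask",
    "save_measurement",
    "load_measurement",
]

_PEAK = {np.dtype("uint8"): 255.0, np.dtype("uint16"): 65535.0}


def load_image(path: str | Path) -> np.ndarray:
    """Load a grayscale PNG/TIFF as float64 in [0, 1]."""
    path = Path(path)
    arr = tifffile.imread(path) if path.suffix.lower() in {".tif", ".tiff"} else iio.imread(path)
    if arr.ndim != 2:
        raise ValueError(f"expected a single-channel grayscale image, got shape {arr.shape}")
    if arr.dtype in _PEAK:
        return arr.astype(float) / _PEAK[arr.dtype]
    if np.issubdtype(arr.dtype, np.floating):
        return np.clip(arr.astype(float), 0.0, 1.0)
    raise ValueError(f"unsupported image dtype {arr.dtype}")


def save_image(path: str | Path, img: np.ndarray, bit_depth: int = 16) -> None:
    """Save a [0, 1] image as 8/16-bit grayscale PNG or TIFF."""
    path = Path(path)
    img = np.clip(np.asarray(img, dtype=float), 0.0, 1.0)
    if bit_depth == 16:
        arr = np.round(img * 65535.0).astype(np.uint16)
    elif bit_depth == 8:
        arr = np.round(img * 255.0).astype(np.uint8)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def save_mask(path: str | Path, mask: FourierMask) -> None:
    np.save(path, mask.selected)


def load_mask(path: str | Path) -> FourierMask:
    return FourierMask(np.load(path))


def save_measurement(path: str | Path, meas: Measurement) -> None:
    np.save(path, meas.data)
    Path(str(path) + ".json").write_text(json.dumps({"noise_sd": meas.noise_sd}))


def load_measurement(path: str | Path) -> Measurement:
    data = np.load(path)
    side = Path(str(path) + ".json")
    noise_sd = json.loads(side.read_text())["noise_sd"] if side.exists() else 0.0
    return Measurement(data, noise_sd=noise_sd)
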