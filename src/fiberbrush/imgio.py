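"""Grayscale image I/O: PNG (8-bit) and TIFF (8/16-bit) as floats in [0, 1]."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile


def read_gray(path: str | Path) -> np.ndarray:
    """Read a grayscale image and normalize to float64 in [0, 1]."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:  # collapse RGB(A) to luminance if needed
        arr = arr[..., :3].mean(axis=-1)
    if np.issubdtype(arr.dtype, np.integer):
        peak = float(np.iinfo(arr.dtype).max)
        return arr.astype(np.float64) / peak
    return np.clip(arr.astype(np.float64), 0.0, 1.0)


def write_gray(path: str | Path, image: np.ndarray, bit_depth: int = 8) -> None:
    """Write a [0, 1] float image as 8-bit PNG/TIFF or 16-bit TIFF."""
    path = Path(path)
    image = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    if bit_depth == 8:
        data = np.round(image * 255).astype(np.uint8)
    elif bit_depth == 16:
        data = np.round(image * 65535).astype(np.uint16)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    else:
        if bit_depth == 16:
            raise ValueError("16-bit output requires a TIFF path")
        iio.imwrite(path, data)
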