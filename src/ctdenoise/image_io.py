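"""Reading and writing grayscale images (PNG / TIFF, 8- or 16-bit).

Integer images are normalized to [0, 1] on read (8-bit: /255, 16-bit:
/65535); floating TIFFs pass through unchanged.  Writing inverts the
scaling with round-half-even and clips to the valid range — the only
place in the package where clipping happens.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import ParameterError
from .image import GrayImage, as_gray_image

__all__ = ["read_image", "write_image", "write_float_tiff"]


def read_image(path: str | Path) -> GrayImage:
    """Read a single-channel PNG/TIFF; multichannel inputs use channel 0 with a warning."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        warnings.warn(f"{path}: multichannel image, using first channel", stacklevel=2)
        arr = arr[..., 0]
    if arr.ndim != 2:
        raise ParameterError(f"{path}: unsupported image dimensionality {arr.ndim}")
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    if np.issubdtype(arr.dtype, np.floating):
        return as_gray_image(arr)
    raise ParameterError(f"{path}: unsupported pixel dtype {arr.dtype}")


def write_image(img: GrayImage, path: str | Path, bit_depth: int = 16) -> None:
    """Write to PNG/TIFF at the given bit depth (8 or 16), clipping to [0, 1]."""
    img = as_gray_image(img)
    if bit_depth == 8:
        peak, dtype = 255, np.uint8
    elif bit_depth == 16:
        peak, dtype = 65535, np.uint16
    else:
        raise ParameterError(f"bit_depth must be 8 or 16, got {bit_depth}")
    path = Path(path)
    if path.suffix.lower() == ".png" and bit_depth == 16:
        # imageio's default PNG plugin writes 16-bit fine; nothing special needed
        pass
    quantized = np.rint(np.clip(img, 0.0, 1.0) * peak).astype(dtype)
    iio.imwrite(path, quantized)


def write_float_tiff(img: GrayImage, path: str | Path) -> None:
    """Write a float32 TIFF without quantization (for signed intermediates)."""
    tifffile.imwrite(Path(path), np.asarray(img, dtype=np.float32))
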