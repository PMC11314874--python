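"""Reading and writing raster images and slice stacks.

Supports 8- and 16-bit, single-channel and RGB data.  PNG handles 8-bit
images and 16-bit greyscale; 16-bit RGB goes to TIFF (the PNG codec in
the underlying Pillow backend has no 16-bit RGB mode).  Stacks are stored
as multi-page TIFF, or read from a directory of ordered single images.

All round trips are lossless: what is written is read back bit-identical.
No LIP arithmetic happens here — conversion between stored intensities
and tones lives in :mod:`lipimage.core`.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .core import GreyScale, IntensityImage, LIPError, from_tone, to_tone
from .interp import SliceStack

__all__ = ["read_image", "write_image", "read_stack", "write_stack"]

_VALID_DTYPES = (np.uint8, np.uint16)


def _check_array(arr: np.ndarray, origin: str) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.dtype not in _VALID_DTYPES:
        raise LIPError(
            f"{origin}: unsupported sample type {arr.dtype}; "
            "supported bit depths are 8 (uint8) and 16 (uint16)"
        )
    if arr.ndim == 3 and arr.shape[-1] == 4:  # drop alpha, keep RGB
        arr = arr[..., :3]
    if arr.ndim not in (2, 3) or (arr.ndim == 3 and arr.shape[-1] != 3):
        raise LIPError(
            f"{origin}: expected a 2-D greyscale or (H, W, 3) RGB array, "
            f"got shape {arr.shape}"
        )
    return arr


def read_image(path) -> IntensityImage:
    """Read a PNG or TIFF image as stored intensities (uint8/uint16)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    return IntensityImage(_check_array(arr, str(path)))


def write_image(img: IntensityImage, path) -> None:
    """Write an intensity image; format chosen from the file extension."""
    path = Path(path)
    arr = img.values
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
        return
    if arr.dtype == np.uint16 and arr.ndim == 3:
        raise LIPError(
            f"{path}: 16-bit RGB is not representable as PNG here; use .tif"
        )
    iio.imwrite(path, arr)


def _stack_from_array(arr: np.ndarray, origin: str, spacing: float, pixel_size: float,
                      scale: GreyScale | None) -> SliceStack:
    if arr.ndim not in (3, 4):
        raise LIPError(f"{origin}: expected a multi-page image, got shape {arr.shape}")
    slices = []
    for page in arr:
        img = IntensityImage(_check_array(page, origin))
        slices.append(to_tone(img, scale))
    return SliceStack(slices, spacing=spacing, pixel_size=pixel_size)


def read_stack(path, spacing: float = 1.0, pixel_size: float = 1.0,
               scale: GreyScale | None = None) -> SliceStack:
    """Read an ordered slice stack as tone images.

    ``path`` is either a multi-page TIFF or a directory whose images are
    taken in lexicographic filename order.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir()
            if p.suffix.lower() in (".png", ".tif", ".tiff")
        )
        if len(files) < 2:
            raise LIPError(f"{path}: a stack directory needs at least 2 images")
        slices = [to_tone(read_image(p), scale) for p in files]
        return SliceStack(slices, spacing=spacing, pixel_size=pixel_size)
    arr = tifffile.imread(path)
    return _stack_from_array(arr, str(path), spacing, pixel_size, scale)


def write_stack(stack: SliceStack, path) -> None:
    """Write a slice stack as a multi-page TIFF (tones quantized per page)."""
    pages = np.stack([from_tone(s).values for s in stack.slices])
    photometric = "rgb" if pages.ndim == 4 else "minisblack"
    tifffile.imwrite(Path(path), pages, photometric=photometric)
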