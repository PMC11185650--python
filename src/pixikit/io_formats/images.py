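"""Raster image readers: PNG/JPEG, hyperstack TIFF, uncompressed DICOM.

Every reader returns an :class:`~pixikit.project.ImageItem` with pixels in
(z, channel, y, x) order and intensities scaled to [0, 1] by the source bit
depth, so a b-bit integer v maps to v / (2**b - 1) and scaling is invertible
for bit depths <= 16.

TIFF pages are interpreted channel-fastest: a file with z*c pages declared as
c channels becomes planes [(z0,c0), (z0,c1), ..., (z1,c0), ...].
"""

from __future__ import annotations

import os
from typing import Optional

import imageio.v3 as iio
import numpy as np
import tifffile

from ..errors import UnsupportedFormatError, ValidationError
from ..project import ImageItem

_BIT_DEPTH = {np.dtype(np.uint8): 8, np.dtype(np.uint16): 16, np.dtype(np.int16): 16}


def _scale(arr: np.ndarray, bit_depth: int) -> np.ndarray:
    return arr.astype(float) / (2**bit_depth - 1)


def read_image(
    path, declared_channels: Optional[int] = None, image_id: Optional[str] = None
) -> ImageItem:
    """Read PNG/JPEG/TIFF/DICOM into a normalized (z, channel, y, x) image.

    ``declared_channels`` factors a multi-page TIFF stack into z-planes; a
    page count not divisible by it is an error.
    """
    path = os.fspath(path)
    name = os.path.basename(path)
    image_id = image_id or name
    ext = os.path.splitext(path)[1].lower()

    if ext in (".png", ".jpg", ".jpeg"):
        arr = iio.imread(path)
        bit_depth = _BIT_DEPTH.get(arr.dtype, 8)
        if arr.ndim == 2:
            pixels = _scale(arr, bit_depth)[None, None]
        else:
            arr = arr[:, :, :3]  # drop alpha
            pixels = _scale(arr, bit_depth).transpose(2, 0, 1)[None]
        return ImageItem(id=image_id, name=name, pixels=pixels, bit_depth=bit_depth)

    if ext in (".tif", ".tiff"):
        arr = tifffile.imread(path)
        bit_depth = _BIT_DEPTH.get(arr.dtype, 8)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise UnsupportedFormatError(
                f"TIFF with shape {arr.shape} is not a page stack"
            )
        c = declared_channels or 1
        pages = arr.shape[0]
        if pages % c != 0:
            raise ValidationError(
                f"page count {pages} is not divisible by declared_channels={c}"
            )
        pixels = _scale(arr, bit_depth).reshape(pages // c, c, *arr.shape[1:])
        return ImageItem(id=image_id, name=name, pixels=pixels, bit_depth=bit_depth)

    if ext == ".dcm":
        return _read_dicom(path, image_id, name)

    raise UnsupportedFormatError(f"unsupported image format {ext!r}")


def _read_dicom(path: str, image_id: str, name: str) -> ImageItem:
    import pydicom

    ds = pydicom.dcmread(path)
    syntax = getattr(ds.file_meta, "TransferSyntaxUID", None)
    if syntax is not None and syntax.is_compressed:
        raise UnsupportedFormatError(
            f"compressed DICOM transfer syntax {syntax} is not supported"
        )
    arr = ds.pixel_array.astype(float)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    arr = arr * slope + intercept
    bit_depth = int(getattr(ds, "BitsStored", 16))
    pixels = np.clip(arr / (2**bit_depth - 1), 0.0, 1.0)
    if pixels.ndim != 2:
        raise UnsupportedFormatError("only single-frame grayscale DICOM is supported")
    return ImageItem(
        id=image_id, name=name, pixels=pixels[None, None], bit_depth=bit_depth
    )


def to_integer_pixels(item: ImageItem) -> np.ndarray:
    """Invert the bit-depth scaling (exact for bit depths <= 16)."""
    scale = 2**item.bit_depth - 1
    return np.rint(item.pixels * scale).astype(np.uint16 if item.bit_depth > 8 else np.uint8)
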