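"""Image container and grayscale raster I/O.

All image math in this package runs on 2-D non-negative intensity grids.
:class:`ImageRaster` wraps the pixel array together with the bit depth it was
read at and an optional physical pixel size; intensities are kept at native
depth on disk and converted to floating point only inside the algorithms, so
no quantization is introduced before thresholding or focus measurement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

__all__ = ["ImageRaster", "read_raster", "write_raster"]

#: minimum side length of a field accepted for analysis
MIN_FIELD_SIDE = 8


@dataclass
class ImageRaster:
    """A 2-D grayscale intensity grid.

    Parameters
    ----------
    pixels
        2-D array of finite, non-negative intensities (arbitrary units).
    bit_depth
        8, 16 or the string ``"float"``; records the acquisition depth.
    pixel_size_um
        Physical pixel size in micrometres, if known.
    """

    pixels: np.ndarray
    bit_depth: int | str = "float"
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D image, got shape {self.pixels.shape}")
        if not np.isfinite(self.pixels).all():
            raise ValueError("image contains non-finite intensities")
        if (self.pixels < 0).any():
            raise ValueError("image contains negative intensities")
        if self.bit_depth not in (8, 16, "float"):
            raise ValueError(f"unsupported bit depth {self.bit_depth!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def as_float(self) -> np.ndarray:
        """Pixel data as float64 (copy only when needed)."""
        return np.asarray(self.pixels, dtype=np.float64)

    def check_analyzable(self) -> None:
        """Raise if the field is too small to analyze."""
        h, w = self.shape
        if h < MIN_FIELD_SIDE or w < MIN_FIELD_SIDE:
            raise ValueError(
                f"field of shape {h}x{w} is below the minimum analyzable size "
                f"{MIN_FIELD_SIDE}x{MIN_FIELD_SIDE}"
            )


def _depth_of_dtype(dtype: np.dtype) -> int | str:
    if dtype == np.uint8:
        return 8
    if dtype == np.uint16:
        return 16
    return "float"


def read_raster(path: str | Path, pixel_size_um: float | None = None) -> ImageRaster:
    """Read a grayscale TIFF or PNG image from disk.

    Multi-sample images are rejected: the pipeline expects one channel per
    file (projections and channel splitting happen upstream).
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel 2-D image, got shape {arr.shape}")
    return ImageRaster(arr, bit_depth=_depth_of_dtype(arr.dtype), pixel_size_um=pixel_size_um)


def write_raster(raster: ImageRaster, path: str | Path) -> None:
    """Write a raster to TIFF (lossless at native depth) or PNG."""
    path = Path(path)
    arr = np.asarray(raster.pixels)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        if arr.dtype not in (np.uint8, np.uint16):
            warnings.warn("writing float image to PNG rescales to 8-bit", stacklevel=2)
            lo, hi = float(arr.min()), float(arr.max())
            scale = 255.0 / (hi - lo) if hi > lo else 0.0
            arr = ((arr - lo) * scale).astype(np.uint8)
        Image.fromarray(arr).save(path)
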