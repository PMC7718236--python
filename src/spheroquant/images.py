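"""Light-weight containers for micrographs.

Images carry their bit depth (8 or 16) and the physical pixel size in
micrometers per pixel, which every downstream measurement needs.  Pixel
arrays are kept as plain numpy arrays; intensities live on the native
``[0, 2**bit_depth - 1]`` scale and are never silently rescaled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "IntensityImage",
    "RGBImage",
    "to_gray",
    "load_image",
    "save_image",
]


def _check_scale(pixels: np.ndarray, bit_depth: int, pixel_size: float) -> None:
    if bit_depth not in (8, 16):
        raise ValueError(f"bit_depth must be 8 or 16, got {bit_depth}")
    if not pixel_size > 0:
        raise ValueError(f"pixel_size must be positive, got {pixel_size}")
    if pixels.size == 0:
        raise ValueError("empty image")
    maxval = 2**bit_depth - 1
    if float(pixels.max(initial=0)) > maxval:
        raise ValueError(f"intensities exceed {maxval} for {bit_depth}-bit image")
    if float(pixels.min(initial=0)) < 0:
        raise ValueError("negative intensities")


@dataclass(frozen=True)
class IntensityImage:
    """Single-channel 2-D micrograph.

    Parameters
    ----------
    pixels : ndarray, shape (H, W)
        Nonnegative intensities on the native bit-depth scale.
    bit_depth : {8, 16}
    pixel_size : float
        Micrometers per pixel.
    """

    pixels: np.ndarray
    bit_depth: int = 8
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"expected 2-D single-channel image, got shape {px.shape}")
        object.__setattr__(self, "pixels", px)
        _check_scale(px, self.bit_depth, self.pixel_size)

    @property
    def maxval(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class RGBImage:
    """2-D micrograph with (R, G, B) channels stacked on the last axis."""

    pixels: np.ndarray
    bit_depth: int = 8
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[-1] != 3:
            raise ValueError(f"expected (H, W, 3) RGB image, got shape {px.shape}")
        object.__setattr__(self, "pixels", px)
        _check_scale(px, self.bit_depth, self.pixel_size)

    @property
    def maxval(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]  # type: ignore[return-value]


def to_gray(image: RGBImage | IntensityImage) -> IntensityImage:
    """Channel-average (luminance-free) grayscale conversion.

    A plain mean of R, G and B is used: for segmentation the relevant
    contrast is object vs background, not perceptual luminance.
    """
    if isinstance(image, IntensityImage):
        return image
    gray = np.asarray(image.pixels, dtype=np.float64).mean(axis=-1)
    return IntensityImage(gray, bit_depth=image.bit_depth, pixel_size=image.pixel_size)


def load_image(path: str | Path, pixel_size: float = 1.0) -> IntensityImage | RGBImage:
    """Read a TIFF/PNG micrograph, dispatching on channel count.

    Bit depth is inferred from the dtype (uint16 -> 16-bit, else 8-bit).
    """
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    bit_depth = 16 if arr.dtype == np.uint16 else 8
    if arr.ndim == 3 and arr.shape[-1] >= 3:
        return RGBImage(arr[..., :3], bit_depth=bit_depth, pixel_size=pixel_size)
    return IntensityImage(arr, bit_depth=bit_depth, pixel_size=pixel_size)


def save_image(image: IntensityImage | RGBImage | np.ndarray, path: str | Path) -> None:
    """Write an image as TIFF (or PNG by extension) on its integer scale."""
    path = Path(path)
    arr = image if isinstance(image, np.ndarray) else image.pixels
    if not np.issubdtype(arr.dtype, np.integer):
        bit_depth = 8 if isinstance(image, np.ndarray) else image.bit_depth
        dtype = np.uint8 if bit_depth == 8 else np.uint16
        arr = np.clip(np.rint(arr), 0, 2**bit_depth - 1).astype(dtype)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(path, arr)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, arr)
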