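"""Spheroid / cryosection segmentation and size measurement.

The segmentation is deliberately simple — Gaussian smoothing, Otsu
threshold, hole filling, small-object and border-leak removal, largest
connected component — because spheroid imagery is high-contrast: a dark
spheroid on a bright slide (bright-field), or a stained section on a
white slide.  Size is reported as the *equivalent circular diameter*
``2 * pixel_size * sqrt(area / pi)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import cached_property

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure
from skimage.filters import gaussian, threshold_otsu

from .images import IntensityImage, RGBImage, to_gray

__all__ = ["SpheroidMask", "segment_section", "measure_diameter", "growth_table",
           "NoObjectFound", "AmbiguousObjectWarning"]


class NoObjectFound(ValueError):
    """No connected component survived thresholding and filtering."""


class AmbiguousObjectWarning(UserWarning):
    """A second component is more than half the size of the largest."""


@dataclass(frozen=True)
class SpheroidMask:
    """Boolean region identifying one spheroid or section."""

    mask: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2 or not m.any():
            raise ValueError("mask must be a nonempty 2-D boolean region")
        object.__setattr__(self, "mask", m)

    @property
    def area(self) -> int:
        """Region area in px^2."""
        return int(self.mask.sum())

    @cached_property
    def centroid(self) -> tuple[float, float]:
        ys, xs = np.nonzero(self.mask)
        return float(ys.mean()), float(xs.mean())

    @property
    def equivalent_diameter(self) -> float:
        """Diameter (µm) of the circle with the region's area."""
        return 2.0 * self.pixel_size * float(np.sqrt(self.area / np.pi))

    @cached_property
    def boundary(self) -> np.ndarray:
        """Ordered (row, col) contour of the region at the 0.5 level."""
        contours = measure.find_contours(self.mask.astype(float), 0.5)
        return max(contours, key=len)


def segment_section(
    image: IntensityImage | RGBImage,
    polarity: str = "dark_object",
    sigma: float = 2.0,
    min_object_fraction: float = 0.001,
    border_reject_fraction: float = 0.5,
) -> SpheroidMask:
    """Locate the spheroid/section as the largest thresholded component.

    Parameters
    ----------
    polarity : {"dark_object", "bright_object"}
        Which side of the Otsu threshold the object lies on
        (bright-field spheroids and stained sections are dark on a
        bright slide; fluorescent sections are bright on black).
    sigma : float
        Gaussian pre-smoothing in px.
    min_object_fraction : float
        Components smaller than this fraction of the field are debris.
    border_reject_fraction : float
        Components touching at least this fraction of the image border
        are treated as background leakage and rejected.

    Raises
    ------
    NoObjectFound
        If no component survives the filters.

    Warns
    -----
    AmbiguousObjectWarning
        If the runner-up component exceeds half the largest one.
    """
    if polarity not in {"dark_object", "bright_object"}:
        raise ValueError(f"unknown polarity {polarity!r}")
    gray = to_gray(image)
    smoothed = gaussian(np.asarray(gray.pixels, dtype=np.float64),
                        sigma=sigma, preserve_range=True)
    if smoothed.max() == smoothed.min():
        raise NoObjectFound("uniform image: nothing to segment")
    thr = threshold_otsu(smoothed)
    binary = smoothed < thr if polarity == "dark_object" else smoothed > thr
    binary = ndimage.binary_fill_holes(binary)
    h, w = binary.shape
    min_size = max(1, int(min_object_fraction * h * w))

    labels, n = ndimage.label(binary)
    if n == 0:
        raise NoObjectFound("no component above the threshold")
    border = np.zeros_like(binary)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    border_len = int(border.sum())
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = []
    for lab in range(1, n + 1):
        if sizes[lab - 1] < min_size:
            continue  # debris
        touch = int(np.count_nonzero(border & (labels == lab)))
        if touch / border_len < border_reject_fraction:
            keep.append(lab)
    if not keep:
        raise NoObjectFound("all components rejected as border leakage")
    keep_sizes = sorted(((sizes[lab - 1], lab) for lab in keep), reverse=True)
    if len(keep_sizes) > 1 and keep_sizes[1][0] > 0.5 * keep_sizes[0][0]:
        warnings.warn("second-largest component exceeds half the largest",
                      AmbiguousObjectWarning, stacklevel=2)
    best = keep_sizes[0][1]
    return SpheroidMask(labels == best, pixel_size=image.pixel_size)


def measure_diameter(mask: SpheroidMask) -> float:
    """Equivalent circular diameter of the mask, in µm."""
    return mask.equivalent_diameter


def growth_table(measurements: pd.DataFrame) -> pd.DataFrame:
    """Summarize growth-kinetics diameter measurements.

    ``measurements`` needs columns ``condition``, ``day`` and
    ``diameter`` (µm); a ``replicate`` column is accepted and ignored.
    Returns one row per (condition, day) with the group mean, sample SD
    (n-1 denominator; missing when n = 1) and n.
    """
    required = {"condition", "day", "diameter"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if (measurements["diameter"] < 0).any():
        raise ValueError("negative diameters")
    out = (
        measurements.groupby(["condition", "day"], sort=True)["diameter"]
        .agg(mean="mean", sd=lambda x: x.std(ddof=1), n="count")
        .reset_index()
    )
    return out
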