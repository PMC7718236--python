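"""Concentric-rim radial fluorescence profiling.

The section is decomposed into ``n_rims`` (default 50) concentric rims
of equal width in the *normalized radial coordinate* r, where r = 0 at
the section centroid and r = 1 on its boundary — the discrete analogue
of shrinking the outline by a constant diameter step per rim.  Three
geometries define r for a pixel:

``star_convex`` (default)
    distance to the centroid divided by the boundary distance along the
    same direction, so irregular but star-convex outlines keep rim 50
    hugging the true boundary.  The boundary distance along a direction
    is found by marching the ray from the centroid in 0.5 px steps and
    taking the farthest step whose nearest pixel is inside the mask —
    a discrete, exactly reproducible definition.
``circular``
    distance to the centroid divided by the equivalent circular radius,
    clipped to 1 (a strict disk approximation).
``edt``
    1 - (Euclidean distance to the boundary / maximum such distance);
    the fallback for masks that are not star-convex about the centroid.

Per-rim mean intensities form the radial profile; profiles are
normalized to sum to 1 so sections of different overall brightness are
comparable.  Replicate cryosections aggregate to mean +/- sample SD per
rim, and two groups are compared rim by rim with Welch's t-test, with a
Holm-adjusted p-value reported alongside the raw one because 50
simultaneous tests are performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from statsmodels.stats.multitest import multipletests

from .images import IntensityImage
from .segmentation import SpheroidMask
from .stats import welch_ttest

__all__ = ["RimMap", "RadialProfile", "ProfileGroup", "RimComparison",
           "compute_rims", "radial_profile", "aggregate_profiles",
           "compare_profiles", "CentroidOutsideMask", "EmptyRimWarning",
           "AllZeroProfileWarning"]

_RAY_STEP = 0.5  # px, sampling step of the star-convex boundary search


class CentroidOutsideMask(ValueError):
    """The centroid pixel is not inside the mask (mask not star-convex)."""


class EmptyRimWarning(UserWarning):
    pass


class AllZeroProfileWarning(UserWarning):
    """Total intensity in the mask is zero; normalized profile undefined."""


@dataclass(frozen=True)
class RimMap:
    """Per-pixel rim labels 1..n_rims (0 outside the mask)."""

    labels: np.ndarray
    n_rims: int
    mode: str
    bin_edges: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class RadialProfile:
    """Per-rim mean intensities of one cryosection and their normalizations."""

    rim_means: np.ndarray
    n_pixels_per_rim: np.ndarray
    source_id: str = ""

    @property
    def n_rims(self) -> int:
        return len(self.rim_means)

    @property
    def normalized(self) -> Optional[np.ndarray]:
        """Sum-to-one normalization p_i = m_i / sum_j m_j (None if all zero)."""
        total = self.rim_means.sum()
        if total == 0:
            return None
        return self.rim_means / total

    @property
    def max_normalized(self) -> Optional[np.ndarray]:
        """Max-to-one normalization (alternative reading of the protocol)."""
        peak = self.rim_means.max()
        if peak == 0:
            return None
        return self.rim_means / peak

    @property
    def mass_fraction(self) -> Optional[np.ndarray]:
        """Fraction of total integrated intensity per rim.

        Weighting each rim mean by its pixel count turns the profile
        into the intensity-weighted histogram of pixel radial
        coordinates — the quantity that matches the generator's
        ``rim_density`` ground truth.
        """
        mass = self.rim_means * self.n_pixels_per_rim
        total = mass.sum()
        if total == 0:
            return None
        return mass / total


@dataclass(frozen=True)
class ProfileGroup:
    """Replicate profiles of one condition with per-rim mean and sample SD."""

    profiles: tuple[RadialProfile, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.profiles) < 2:
            raise ValueError("a profile group needs at least 2 cryosections")
        n_rims = {p.n_rims for p in self.profiles}
        if len(n_rims) != 1:
            raise ValueError(f"mixed rim counts in group: {sorted(n_rims)}")

    @property
    def n(self) -> int:
        return len(self.profiles)

    @property
    def n_rims(self) -> int:
        return self.profiles[0].n_rims

    @property
    def values(self) -> np.ndarray:
        """(n_sections, n_rims) matrix of normalized profiles."""
        rows = []
        for p in self.profiles:
            v = p.normalized
            rows.append(np.full(p.n_rims, np.nan) if v is None else v)
        return np.array(rows)

    @property
    def mean(self) -> np.ndarray:
        return np.nanmean(self.values, axis=0)

    @property
    def sd(self) -> np.ndarray:
        return np.nanstd(self.values, axis=0, ddof=1)


@dataclass(frozen=True)
class RimComparison:
    """Rim-by-rim two-group comparison (Welch t per rim)."""

    table: pd.DataFrame  # rim, mean_A, sd_A, mean_B, sd_B, t, df, p_raw, p_holm, significant
    alpha: float = 0.05
    label_a: str = "A"
    label_b: str = "B"

    @property
    def significant_rims(self) -> np.ndarray:
        return self.table.loc[self.table["significant"], "rim"].to_numpy()


# ---------------------------------------------------------------------------
# rim assignment


def _star_convex_labels(mask: np.ndarray, centroid: tuple[float, float],
                        n_rims: int) -> np.ndarray:
    """Vectorized ray-march rim assignment.

    For every in-mask pixel the boundary distance R along its direction
    from the centroid is the largest t in {step, 2*step, ...} whose
    nearest-pixel sample lies inside the mask; the pixel's normalized
    radius is min(1, |d| / R).  All arithmetic is double precision so a
    per-pixel scalar re-implementation reproduces the labels exactly.
    """
    h, w = mask.shape
    cy, cx = centroid
    ys, xs = np.nonzero(mask)
    dy = ys - cy
    dx = xs - cx
    norm = np.sqrt(dy * dy + dx * dx)
    nz = norm > 0
    safe = np.where(nz, norm, 1.0)
    uy = dy / safe
    ux = dx / safe

    kmax = int(np.ceil((norm.max() + 1.0) / _RAY_STEP))
    boundary_t = np.zeros_like(norm)
    for k in range(1, kmax + 1):
        t = k * _RAY_STEP
        rr = np.floor(cy + t * uy + 0.5).astype(np.int64)
        cc = np.floor(cx + t * ux + 0.5).astype(np.int64)
        ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        inside = np.zeros(len(ys), dtype=bool)
        inside[ok] = mask[rr[ok], cc[ok]]
        boundary_t[inside] = t

    r = np.where(nz, norm / np.maximum(boundary_t, _RAY_STEP), 0.0)
    r = np.minimum(r, 1.0)
    lab = np.minimum(n_rims, np.floor(r * n_rims).astype(np.int64) + 1)
    labels = np.zeros(mask.shape, dtype=np.int64)
    labels[ys, xs] = lab
    return labels


def _circular_labels(mask: np.ndarray, centroid: tuple[float, float],
                     n_rims: int) -> np.ndarray:
    h, w = mask.shape
    cy, cx = centroid
    ys, xs = np.nonzero(mask)
    r_eq = np.sqrt(mask.sum() / np.pi)
    norm = np.sqrt((ys - cy) ** 2 + (xs - cx) ** 2)
    r = np.minimum(norm / r_eq, 1.0)
    lab = np.minimum(n_rims, np.floor(r * n_rims).astype(np.int64) + 1)
    labels = np.zeros(mask.shape, dtype=np.int64)
    labels[ys, xs] = lab
    return labels


def _edt_labels(mask: np.ndarray, n_rims: int) -> np.ndarray:
    dist = ndimage.distance_transform_edt(mask)
    dmax = dist.max()
    r = 1.0 - dist / dmax
    lab = np.minimum(n_rims, np.floor(r * n_rims).astype(np.int64) + 1)
    labels = np.where(mask, lab, 0).astype(np.int64)
    return labels


def compute_rims(mask: SpheroidMask | np.ndarray, n_rims: int = 50,
                 mode: str = "star_convex") -> RimMap:
    """Assign every in-mask pixel to one of ``n_rims`` concentric rims.

    Rim 1 is the center, rim ``n_rims`` hugs the boundary; bins are
    equal-width in the normalized radial coordinate of the chosen
    geometry (see module docstring).

    Raises
    ------
    CentroidOutsideMask
        In ``star_convex`` mode when the centroid pixel is outside the
        mask; choose ``edt`` for such masks (no automatic fallback).
    """
    if n_rims < 2:
        raise ValueError("n_rims must be at least 2")
    if not isinstance(mask, SpheroidMask):
        mask = SpheroidMask(mask)
    m = mask.mask
    if mode == "star_convex":
        cy, cx = mask.centroid
        if not m[int(round(cy)), int(round(cx))]:
            raise CentroidOutsideMask(
                "centroid falls outside the mask; use mode='edt'")
        labels = _star_convex_labels(m, (cy, cx), n_rims)
    elif mode == "circular":
        labels = _circular_labels(m, mask.centroid, n_rims)
    elif mode == "edt":
        labels = _edt_labels(m, n_rims)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return RimMap(labels=labels, n_rims=n_rims, mode=mode,
                  bin_edges=np.linspace(0.0, 1.0, n_rims + 1))


# ---------------------------------------------------------------------------
# profiles


def radial_profile(image: IntensityImage | np.ndarray, rim_map: RimMap,
                   source_id: str = "") -> RadialProfile:
    """Mean intensity per rim, plus pixel counts.

    Rims with no pixels contribute a mean of 0 (with a warning) so the
    profile keeps its fixed length.  If the whole-section intensity sum
    is zero an :class:`AllZeroProfileWarning` is issued and the
    normalized profile is ``None``.
    """
    pixels = image.pixels if isinstance(image, IntensityImage) else np.asarray(image)
    if pixels.shape != rim_map.labels.shape:
        raise ValueError("image and rim map shapes differ")
    vals = np.asarray(pixels, dtype=np.float64).ravel()
    labs = rim_map.labels.ravel()
    n = rim_map.n_rims
    counts = np.bincount(labs, minlength=n + 1)[1:n + 1]
    sums = np.bincount(labs, weights=vals, minlength=n + 1)[1:n + 1]
    if (counts == 0).any():
        warnings.warn(f"{int((counts == 0).sum())} empty rim(s); mean set to 0",
                      EmptyRimWarning, stacklevel=2)
    means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    if means.sum() == 0:
        warnings.warn("all-zero profile: normalization undefined",
                      AllZeroProfileWarning, stacklevel=2)
    return RadialProfile(rim_means=means, n_pixels_per_rim=counts,
                         source_id=source_id)


def aggregate_profiles(profiles: Sequence[RadialProfile],
                       label: str = "") -> ProfileGroup:
    """Bundle replicate cryosection profiles into one condition group."""
    return ProfileGroup(profiles=tuple(profiles), label=label)


def compare_profiles(group_a: ProfileGroup, group_b: ProfileGroup,
                     alpha: float = 0.05) -> RimComparison:
    """Welch two-sample t-test per rim on normalized profile values.

    The significance flag uses the *raw* per-rim p-value at ``alpha``
    (the convention of per-point testing in profile plots); the
    Holm-adjusted p-value is reported alongside.  A rim where both
    groups have zero variance and equal means has an undefined t and is
    reported with p = 1.
    """
    if group_a.n_rims != group_b.n_rims:
        raise ValueError("groups have different rim counts")
    va, vb = group_a.values, group_b.values
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(group_a.n_rims):
            res = welch_ttest(va[:, i], vb[:, i], alpha=alpha)
            rows.append((i + 1, va[:, i].mean(), va[:, i].std(ddof=1),
                         vb[:, i].mean(), vb[:, i].std(ddof=1),
                         res.statistic, res.df, res.p_value))
    table = pd.DataFrame(rows, columns=["rim", "mean_A", "sd_A", "mean_B",
                                        "sd_B", "t", "df", "p_raw"])
    table["p_holm"] = multipletests(table["p_raw"].to_numpy(), method="holm")[1]
    table["significant"] = table["p_raw"] < alpha
    return RimComparison(table=table, alpha=alpha,
                         label_a=group_a.label or "A",
                         label_b=group_b.label or "B")
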