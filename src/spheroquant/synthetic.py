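"""Seeded synthetic spheroid micrographs with exact ground truth.

Real cryosection data for this kind of assay are rarely shareable, so the
package ships a generator that emulates the three image classes the
analysis consumes:

* single-channel fluorescence sections — a dim autofluorescent disk
  carrying bright, blurred clusters of membrane-dye-labeled cells whose
  radial placement follows a controllable 50-bin density (central,
  uniform, peripheral, or fully custom);
* RGB stained sections — collagen fibers drawn as red curvilinear
  strokes over a yellow cytoplasm background on a white slide, covering a
  requested area fraction;
* bright-field whole spheroids — a dark, soft-edged disk on a bright
  background, for size measurement.

Every generated image is paired with a :class:`GroundTruth` holding the
true section mask, equivalent diameter and, where applicable, the
realized radial label density and collagen pixel fraction — measured
from the rendered image, never echoed from the request — so that each
analysis stage can be tested as a recovery problem.

All randomness flows from ``SectionSpec.seed`` through one
``numpy.random.Generator``; identical specs produce bit-identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .images import IntensityImage, RGBImage

__all__ = ["SectionSpec", "GroundTruth", "N_RIM_BINS",
           "generate_fluorescence_section", "generate_stained_section",
           "generate_brightfield_spheroid"]

#: Number of radial bins used for label densities, matching the 50
#: concentric rims of the profiling stage.
N_RIM_BINS = 50

# Rendering constants on the 8-bit scale (scaled up for 16-bit output).
_AUTOFLUORESCENCE = 12.0     # dim section baseline
_NECROTIC_FACTOR = 0.35      # baseline attenuation inside the necrotic core
_CLUSTER_AMPLITUDE = 140.0   # peak intensity of one labeled-cell cluster
_BF_BACKGROUND = 230.0       # bright-field slide
_BF_OBJECT = 95.0            # bright-field spheroid interior
_CYTOPLASM_RGB = (235.0, 205.0, 60.0)   # yellow: high R, high G, low B
_FIBER_RGB = (205.0, 35.0, 45.0)        # red: high R, low G, low B
_SLIDE_RGB = (255.0, 255.0, 255.0)

# Central/peripheral modes confine cluster centers to a radial band that
# leaves room for the rendered cluster footprint (centers at r <= 0.16
# keep all stamped pixels below r = 0.2 at the default geometry).
_CENTRAL_MAX_R = 0.16
_PERIPHERAL_MIN_R = 0.84


@dataclass
class SectionSpec:
    """Parameters of one synthetic section or spheroid.

    Defaults emulate a mid-sized section: 400 µm equivalent diameter at
    1 µm/px (the emulated biological range is ~170-830 µm), clusters the
    size of single cells (~10 µm across), modest read noise.
    """

    image_size: tuple[int, int] = (480, 480)
    pixel_size: float = 1.0            # µm per pixel
    radius: float = 200.0              # px, nominal section radius
    boundary_irregularity: float = 0.0  # amplitude of low-order radial perturbation
    necrotic_core_fraction: float = 0.0  # fraction of radius, in [0, 1)
    label_mode: str = "uniform"        # central | uniform | peripheral | custom
    label_density: Optional[np.ndarray] = None  # 50 nonnegative bins (custom mode)
    n_clusters: int = 400
    cluster_radius: float = 5.0        # px, rendered cluster footprint
    collagen_fraction: float = 0.15    # target fiber area fraction, in [0, 1]
    fiber_scale: float = 2.0           # px, fiber stroke thickness
    noise_sigma: float = 2.0           # additive Gaussian noise, intensity units
    illumination_gradient: float = 0.0  # fractional intensity drop across the field
    bit_depth: int = 8
    seed: int = 0

    def validate(self) -> None:
        h, w = self.image_size
        if self.radius >= min(h, w) / 2:
            raise ValueError(
                f"radius {self.radius} px does not fit in a {h}x{w} field")
        if not 0 <= self.boundary_irregularity <= 0.3:
            raise ValueError("boundary_irregularity must be in [0, 0.3] "
                             "(larger values break star-convexity)")
        if not 0 <= self.necrotic_core_fraction < 1:
            raise ValueError("necrotic_core_fraction must be in [0, 1)")
        if not 0 <= self.collagen_fraction <= 1:
            raise ValueError("collagen_fraction must be in [0, 1]")
        if self.label_mode not in {"central", "uniform", "peripheral", "custom"}:
            raise ValueError(f"unknown label_mode {self.label_mode!r}")
        if self.label_mode == "custom":
            d = np.asarray(self.label_density, dtype=float)
            if d.shape != (N_RIM_BINS,):
                raise ValueError(f"custom label_density needs {N_RIM_BINS} bins")
            if (d < 0).any():
                raise ValueError("label_density entries must be nonnegative")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.noise_sigma < 0 or self.n_clusters < 0:
            raise ValueError("noise_sigma and n_clusters must be nonnegative")

    @property
    def maxval(self) -> int:
        return 2**self.bit_depth - 1


@dataclass
class GroundTruth:
    """What the generator actually rendered.

    ``rim_density`` is the histogram of the realized cluster radial
    coordinates over the 50 profiling bins, with each cluster weighted
    by its rendered in-section mass, normalized to sum to 1 — i.e. the
    quantity a radial-mass profile of the clean cluster signal recovers
    up to the blur of a single cluster footprint.
    ``collagen_pixel_fraction`` is counted from the rendered fiber mask.
    """

    mask: np.ndarray
    equivalent_diameter: float  # µm
    rim_density: Optional[np.ndarray] = None
    collagen_pixel_fraction: Optional[float] = None
    cluster_centers: Optional[np.ndarray] = None  # (row, col, r_norm) per cluster


# ---------------------------------------------------------------------------
# geometry


def _boundary_harmonics(spec: SectionSpec, rng: np.random.Generator):
    """Low-order (k = 2..5) radial perturbation of the section outline.

    Amplitudes are normalized so the worst-case radial deviation equals
    ``boundary_irregularity``; with amplitude <= 0.3 the outline stays
    star-convex about its center.
    """
    amps = rng.uniform(0.5, 1.0, 4)
    amps *= spec.boundary_irregularity / amps.sum()
    phases = rng.uniform(0.0, 2.0 * np.pi, 4)
    return amps, phases


def _radius_of_angle(theta: np.ndarray, spec: SectionSpec,
                     amps: np.ndarray, phases: np.ndarray) -> np.ndarray:
    out = np.ones_like(theta)
    for k in range(4):
        out = out + amps[k] * np.cos((k + 2) * theta + phases[k])
    return spec.radius * out


def _section_geometry(spec: SectionSpec, rng: np.random.Generator):
    """Per-pixel normalized radial coordinate and the section mask."""
    h, w = spec.image_size
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    amps, phases = _boundary_harmonics(spec, rng)
    yy, xx = np.mgrid[0:h, 0:w]
    dy = yy - cy
    dx = xx - cx
    theta = np.arctan2(dy, dx)
    r_boundary = _radius_of_angle(theta, spec, amps, phases)
    r_norm = np.hypot(dy, dx) / r_boundary
    mask = r_norm <= 1.0
    return mask, r_norm, (cy, cx), (amps, phases)


def _equivalent_diameter(mask: np.ndarray, pixel_size: float) -> float:
    return 2.0 * pixel_size * math.sqrt(mask.sum() / math.pi)


def _illumination(spec: SectionSpec) -> np.ndarray:
    """Mean-preserving horizontal illumination ramp.

    The factor runs linearly from ``1 + g/2`` (left) to ``1 - g/2``
    (right): the total drop across the field is ``g`` while the field
    average stays 1, which is how a flat-field-miscorrected lamp
    gradient presents relative to the calibrated exposure.
    """
    h, w = spec.image_size
    g = spec.illumination_gradient
    cols = np.arange(w, dtype=np.float64)
    factor = 1.0 + g * (0.5 - cols / (w - 1.0))
    return np.broadcast_to(factor, (h, w))


def _finish(spec: SectionSpec, img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Apply illumination, additive Gaussian noise, clip, and quantize."""
    if spec.illumination_gradient != 0.0:
        img = img * _illumination(spec)
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
    return np.clip(np.rint(img), 0, spec.maxval).astype(dtype)


# ---------------------------------------------------------------------------
# fluorescence sections


def _mode_density(spec: SectionSpec) -> np.ndarray:
    """50-bin density of the cluster-center radial coordinate, summing to 1."""
    centers = (np.arange(N_RIM_BINS) + 0.5) / N_RIM_BINS
    if spec.label_mode == "uniform":
        d = np.ones(N_RIM_BINS)
    elif spec.label_mode == "central":
        d = (centers <= _CENTRAL_MAX_R).astype(float)
    elif spec.label_mode == "peripheral":
        d = (centers >= _PERIPHERAL_MIN_R).astype(float)
    else:
        d = np.asarray(spec.label_density, dtype=float).copy()
    if spec.necrotic_core_fraction > 0 and spec.label_mode != "custom":
        d[centers < spec.necrotic_core_fraction] = 0.0
    total = d.sum()
    if total == 0:
        return d
    return d / total


def _sample_radii(density: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Stratified inverse-CDF draw of normalized radii from a 50-bin density.

    Stratified uniforms (one per sample, jittered within its stratum)
    make the realized per-bin counts track ``n * density`` to within one
    count, so the requested density is recoverable even at modest n.
    """
    cdf = np.concatenate([[0.0], np.cumsum(density)])
    cdf[-1] = 1.0
    u = (np.arange(n) + rng.random(n)) / n
    bins = np.searchsorted(cdf, u, side="right") - 1
    bins = np.clip(bins, 0, N_RIM_BINS - 1)
    width = cdf[bins + 1] - cdf[bins]
    frac = np.where(width > 0, (u - cdf[bins]) / np.where(width > 0, width, 1.0),
                    rng.random(n))
    return (bins + frac) / N_RIM_BINS


def _stamp_gaussian(canvas: np.ndarray, mask: np.ndarray, row: float, col: float,
                    amplitude: float, sigma: float) -> float:
    """Add a truncated (3-sigma support) Gaussian blob in place.

    Returns the blob mass that landed inside the mask (the cluster's
    rendered contribution to the section).
    """
    h, w = canvas.shape
    rad = int(math.ceil(3.0 * sigma))
    r0, r1 = max(0, int(row) - rad), min(h, int(row) + rad + 1)
    c0, c1 = max(0, int(col) - rad), min(w, int(col) + rad + 1)
    if r0 >= r1 or c0 >= c1:
        return 0.0
    yy, xx = np.mgrid[r0:r1, c0:c1]
    d2 = (yy - row) ** 2 + (xx - col) ** 2
    blob = amplitude * np.exp(-d2 / (2.0 * sigma**2))
    blob[d2 > (3.0 * sigma) ** 2] = 0.0
    canvas[r0:r1, c0:c1] += blob
    return float(blob[mask[r0:r1, c0:c1]].sum())


def generate_fluorescence_section(spec: SectionSpec) -> tuple[IntensityImage, GroundTruth]:
    """Render a fluorescently labeled cryosection with known radial density.

    The section is a dim autofluorescent region (optionally with a
    darker necrotic core) on a black background.  ``n_clusters`` bright
    Gaussian blobs are placed by sampling the normalized radial
    coordinate from the label density of ``label_mode`` (uniform in
    angle, scaled by the per-angle boundary radius), so the normalized
    radial coordinate of each cluster center is exactly its sampled
    value regardless of boundary irregularity.

    Returns the image and a :class:`GroundTruth` whose ``rim_density``
    is measured from the rendered cluster layer.
    """
    spec.validate()
    density = _mode_density(spec)
    blank = density.sum() == 0
    if spec.n_clusters == 0 and not blank:
        raise ValueError("n_clusters = 0 requires an all-zero custom label_density")
    rng = np.random.default_rng(spec.seed)
    mask, r_norm, (cy, cx), (amps, phases) = _section_geometry(spec, rng)

    layer = np.zeros(spec.image_size, dtype=np.float64)
    centers = np.empty((0, 3))
    rim_density = np.zeros(N_RIM_BINS)
    if not blank and spec.n_clusters > 0:
        radii = _sample_radii(density, spec.n_clusters, rng)
        angles = rng.uniform(0.0, 2.0 * np.pi, spec.n_clusters)
        r_bound = _radius_of_angle(angles, spec, amps, phases)
        rows = cy + radii * r_bound * np.sin(angles)
        cols = cx + radii * r_bound * np.cos(angles)
        amp = _CLUSTER_AMPLITUDE * spec.maxval / 255.0
        sigma = spec.cluster_radius / 2.0
        masses = np.empty(spec.n_clusters)
        for j, (r_, c_) in enumerate(zip(rows, cols)):
            masses[j] = _stamp_gaussian(layer, mask, r_, c_, amp, sigma)
        centers = np.column_stack([rows, cols, radii])
        # Realized radial density: histogram of the realized cluster
        # radial coordinates, each cluster weighted by its rendered
        # in-section mass.
        idx = np.clip((radii * N_RIM_BINS).astype(int), 0, N_RIM_BINS - 1)
        hist = np.bincount(idx, weights=masses, minlength=N_RIM_BINS)
        if hist.sum() > 0:
            rim_density = hist / hist.sum()
    layer[~mask] = 0.0  # labeled structure exists only inside the section

    baseline = _AUTOFLUORESCENCE * spec.maxval / 255.0
    base = np.where(mask, baseline, 0.0)
    if spec.necrotic_core_fraction > 0:
        base[mask & (r_norm < spec.necrotic_core_fraction)] *= _NECROTIC_FACTOR
    pixels = _finish(spec, base + layer, rng)

    truth = GroundTruth(
        mask=mask,
        equivalent_diameter=_equivalent_diameter(mask, spec.pixel_size),
        rim_density=rim_density,
        cluster_centers=centers,
    )
    return IntensityImage(pixels, spec.bit_depth, spec.pixel_size), truth


# ---------------------------------------------------------------------------
# stained sections


def _disk_offsets(radius: float) -> tuple[np.ndarray, np.ndarray]:
    r = max(1, int(math.ceil(radius)))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    keep = yy**2 + xx**2 <= max(1.0, radius**2)
    return yy[keep], xx[keep]


def _draw_fibers(spec: SectionSpec, mask: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    """Random smoothed walks stamped at fiber thickness until the target
    in-section area fraction is reached (within one stroke's increment)."""
    h, w = spec.image_size
    fiber = np.zeros((h, w), dtype=bool)
    section_area = int(mask.sum())
    target = int(round(spec.collagen_fraction * section_area))
    if target == 0:
        return fiber
    ys, xs = np.nonzero(mask)
    off_y, off_x = _disk_offsets(spec.fiber_scale / 2.0)
    n_steps = max(20, int(spec.radius))
    max_strokes = 100000
    for _ in range(max_strokes):
        if np.count_nonzero(fiber & mask) >= target:
            break
        start = rng.integers(len(ys))
        row, col = float(ys[start]), float(xs[start])
        theta = rng.uniform(0.0, 2.0 * np.pi)
        turns = rng.normal(0.0, 0.2, n_steps)
        pts_r = np.empty(n_steps, dtype=np.int64)
        pts_c = np.empty(n_steps, dtype=np.int64)
        for i in range(n_steps):
            theta += turns[i]
            row += math.sin(theta)
            col += math.cos(theta)
            pts_r[i] = int(round(row))
            pts_c[i] = int(round(col))
        rr = (pts_r[:, None] + off_y[None, :]).ravel()
        cc = (pts_c[:, None] + off_x[None, :]).ravel()
        ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        fiber[rr[ok], cc[ok]] = True
    return fiber & mask  # strokes are clipped to the section


def generate_stained_section(spec: SectionSpec) -> tuple[RGBImage, GroundTruth]:
    """Render a Picro-Sirius-Red-like stained section.

    Collagen fibers appear red (high R, low G, low B) as curvilinear
    strokes over a yellow cytoplasm (high R, high G, low B); the slide
    outside the section is white.  Fibers are added stroke by stroke
    until they cover ``collagen_fraction`` of the section pixels; the
    realized fraction is recorded in the ground truth.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    mask, r_norm, _, _ = _section_geometry(spec, rng)
    fiber = _draw_fibers(spec, mask, rng)

    scale = spec.maxval / 255.0
    img = np.empty((*spec.image_size, 3), dtype=np.float64)
    for ch in range(3):
        img[..., ch] = _SLIDE_RGB[ch] * scale
        img[..., ch][mask] = _CYTOPLASM_RGB[ch] * scale
        img[..., ch][fiber] = _FIBER_RGB[ch] * scale

    if spec.illumination_gradient != 0.0:
        img = img * _illumination(spec)[..., None]
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
    pixels = np.clip(np.rint(img), 0, spec.maxval).astype(dtype)

    truth = GroundTruth(
        mask=mask,
        equivalent_diameter=_equivalent_diameter(mask, spec.pixel_size),
        collagen_pixel_fraction=float(np.count_nonzero(fiber) / mask.sum()),
    )
    return RGBImage(pixels, spec.bit_depth, spec.pixel_size), truth


# ---------------------------------------------------------------------------
# bright-field spheroids


def generate_brightfield_spheroid(spec: SectionSpec) -> tuple[IntensityImage, GroundTruth]:
    """Render a whole spheroid under bright-field: dark disk, soft edge,
    bright slide.  Ground-truth diameter is the equivalent circular
    diameter of the rendered mask."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    mask, r_norm, _, _ = _section_geometry(spec, rng)

    scale = spec.maxval / 255.0
    # signed distance (px, positive inward) approximated from the
    # normalized radial coordinate; 3 px smooth transition at the edge
    sd = (1.0 - r_norm) * spec.radius
    alpha = np.clip((sd + 1.5) / 3.0, 0.0, 1.0)
    img = (_BF_BACKGROUND - (_BF_BACKGROUND - _BF_OBJECT) * alpha) * scale
    pixels = _finish(spec, img, rng)

    truth = GroundTruth(
        mask=mask,
        equivalent_diameter=_equivalent_diameter(mask, spec.pixel_size),
    )
    return IntensityImage(pixels, spec.bit_depth, spec.pixel_size), truth
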