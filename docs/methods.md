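# Methods

`spheroquant` quantifies three readouts from 2-D micrographs of
multicellular tumor spheroids (MCTS) and their cryosections: spheroid
size, the radial distribution of a fluorescent cell label, and a
Picro Sirius Red collagen score.  This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
benchmark does and does not establish.

## Size measurement

Spheroids in bright-field are dark, roughly circular objects on a
bright slide.  Segmentation is Gaussian smoothing (σ = 2 px, so the
Otsu threshold is not dominated by shot noise), Otsu thresholding on
the requested polarity, hole filling, removal of components smaller
than 0.1 % of the field (debris; the smallest emulated sections,
~170 µm at 1 µm/px, stay two orders of magnitude above this), and
rejection of components touching ≥ 50 % of the image border
(background leakage).  The largest surviving connected component is the
object; a runner-up larger than half its size triggers an
`AmbiguousObjectWarning` rather than a silent pick.

Size is reported as the *equivalent circular diameter*
`d = 2 · pixel_size · sqrt(area / π)`.  A caliper/Feret diameter would
be an alternative reading of "spheroid diameter"; the area-equivalent
form was chosen because it is insensitive to the direction of mild
asphericity and is the standard regionprops quantity.  On synthetic
spheroids with radii 50–400 px the measured diameter stays within
0.1 % of truth (the guarantee asserted in tests is 2 %, which also
holds at the smallest radii where edge quantization matters most).

Growth kinetics are summarized per (condition, day) as mean, sample SD
(n − 1 denominator, reported missing for n = 1) and n.

## Concentric-rim radial profiling

The profiling statistic is a 50-bin radial decomposition of the
section: conceptually the outline is shrunk toward the centroid in 50
equal steps of the normalized radial coordinate r (equal Δr, not equal
area — successive shrinkage of the boundary by a constant diameter
step is exactly equal-width bins in r).  An equal-area binning was
considered and rejected as the default because it changes the meaning
of "rim i" between sections of different size; the per-rim *mean*
intensity already removes the area dependence.

Three geometries define r for a pixel:

* **star_convex** (default): r = |p − c| / R(θ), where R(θ) is the
  boundary distance from the centroid c along the pixel's own
  direction.  R(θ) is found by marching the ray in 0.5 px steps and
  taking the farthest step whose nearest pixel lies in the mask.  The
  step discretization biases R by at most half a step (≲ 0.3 % of a
  typical radius), uniformly over angles; in exchange the definition
  is exactly reproducible by an independent per-pixel scalar loop,
  which the test suite exploits as a brute-force oracle (labels match
  bit for bit).
* **circular**: r = |p − c| / r_eq with r_eq = sqrt(area/π), clipped
  at 1.  Strict disk approximation.
* **edt**: r = 1 − dist_boundary / max(dist_boundary) from the exact
  Euclidean distance transform; the fallback for masks that are not
  star-convex about their centroid (the star-convex mode raises
  `CentroidOutsideMask` instead of silently degrading).

On a perfect disk the three geometries agree to within one rim almost
everywhere; *exact*-bin agreement saturates near 85–90 %, not ~100 %,
because 50 bins on a 100–200 px radius are sub-pixel-wide in r and any
two independent definitions of r that differ by the ~0.5 px boundary
quantization flip a boundary-adjacent bin.  The cross-mode test
therefore asserts |Δrim| ≤ 1 on ≥ 99 % of pixels; the exact-equality
guarantee is reserved for the per-mode brute-force oracle.

Per rim, the profile is the mean pixel intensity m_i; empty rims keep
m_i = 0 (with a warning) so profiles always have fixed length.  The
default normalization is sum-to-one, p_i = m_i / Σ m_j, which makes
sections of different overall brightness comparable; max-to-one and a
radial-mass variant (m_i weighted by rim pixel count, i.e. the
intensity-weighted histogram of pixel radii) are available as labeled
alternatives.  The radial-mass form is the one that matches the
generator's ground-truth `rim_density` and is used in recovery tests.

Replicates aggregate to per-rim mean ± sample SD.  Two conditions are
compared rim by rim with the two-tailed Welch t-test; the significance
flag follows the per-point convention (raw p < α, default α = 0.05),
and because 50 tests run at once a Holm-adjusted p is always reported
alongside — readers who want family-wise control can use that column
without re-running anything.

## Collagen score

The Picro Sirius Red recipe: invert the RGB image and analyze the
green channel — implemented literally as `maxval − G`, so red fibers
(G low) map high and yellow cytoplasm (G high) maps low, with no
rescaling away from the native 8- or 16-bit range.  "Automatic
background subtraction" is a rolling-ball-style estimate: grayscale
opening with a disk of radius 50 px (the conventional default; the
radius is configurable), computed with a decomposed footprint so large
radii cost little, lightly smoothed (σ = 1 px), clipped under the
image, and subtracted.  The opening removes thin bright structures
(fibers) from the background estimate while following the smooth
cytoplasm level and any illumination gradient, so the corrected image
is essentially fiber prominence.

The score is the **mean corrected intensity over the cryosection
mask** — not an area fraction above threshold, which is provided only
as a labeled alternative (`collagen_area_fraction`).  The section mask
is taken from the image's darkness against the white slide (or passed
in), never from the collagen signal itself: the denominator must be
the cryosection area regardless of how strongly it stained.

A mean-preserving 10 % illumination gradient changes the score by
≤ 5 % (measured: ~1 %) when background subtraction is on; this is the
package's robustness contract for uneven illumination.

## Statistical protocol

Normality: Shapiro–Wilk W (n ≥ 3; constant samples are an error).
Two groups: unpaired two-tailed Welch t-test with Welch–Satterthwaite
degrees of freedom — Welch everywhere a two-sample comparison occurs,
including the rim-wise tests.  Three or more groups: one-way ANOVA
(between/within sum-of-squares decomposition, exact to 1e-9 relative)
followed by Tukey's HSD on all pairs via the studentized-range
distribution.  Significance level 0.05 throughout; stars are rendered
at 0.05/0.01/0.001.  Degenerate inputs (both samples zero-variance
with equal means) report p = 1 with a warning rather than NaN
propagation.  Type-I calibration is tested by simulation: the Welch
rejection rate under the null stays within 0.05 ± 0.015 over 2,000
draws, and the Tukey family-wise error stays ≤ 7 %.

## Synthetic-data generator

The generator is first-class, tested code; its defaults define the
benchmark conditions and are not tuned per test.

* **Geometry.** Sections are disks (default radius 200 px at 1 µm/px,
  i.e. 400 µm diameter, inside the emulated 170–830 µm range) with an
  optional low-order harmonic boundary perturbation (k = 2–5,
  amplitude ≤ 0.3 keeps the outline star-convex) and an optional
  darker necrotic core.
* **Fluorescence.** Labeled cells appear as ~cell-sized Gaussian
  clusters (footprint 5 px ≈ 10 µm, truncated at 3σ) on a dim
  autofluorescence baseline (12/255).  Cluster centers are placed by
  stratified inverse-CDF sampling of the normalized radius from a
  50-bin density — `central` (flat on r ≤ 0.16, chosen so the full
  truncated footprint stays inside r ≤ 0.2), `uniform` (flat in r),
  `peripheral` (flat on r ≥ 0.84) or fully custom — and uniform in
  angle, scaled by the per-angle boundary radius so the sampled r *is*
  the star-convex normalized coordinate.  Stratification keeps
  realized per-bin counts within one of the target, which is what
  makes density recovery a sharp test (max per-bin error ~0.006 at
  1000 clusters, against a 0.03 contract).
* **Ground truth** is always measured from the rendering: the rim
  density is the histogram of realized cluster radii weighted by each
  cluster's rendered in-section mass (clusters clipped at the boundary
  count for what actually landed inside), and the collagen fraction is
  counted from the rendered fiber mask.
* **Staining.** Fibers are random smoothed walks (step 1 px, angular
  diffusion 0.2 rad) stamped at the fiber thickness and clipped to the
  section, added until the target area fraction is reached; the
  construction is monotone in the requested fraction by design.
  Colors: cytoplasm (235, 205, 60), fibers (205, 35, 45), slide white.
* **Noise** is additive Gaussian only (default σ = 2); Poisson shot
  noise was deliberately left out — one fewer parameter, and additive
  noise already exercises every robustness contract the analysis
  makes.  The illumination gradient is a mean-preserving linear ramp
  whose end-to-end drop is the requested fraction.
* **Determinism.** One `numpy.random.Generator` seeded from the spec
  drives everything; identical specs give bit-identical images.

What the generator does *not* emulate: optics (PSF, depth of field),
chromatic effects of real histology, tissue texture inside the
section, cell crowding/exclusion, or 3-D structure.  Passing recovery
tests therefore shows the *analysis* is correct and calibrated on
images whose ground truth is known — it does not certify segmentation
or scoring performance on real slides, where staining variability and
debris dominate.

## Pipeline

Experiments are declared in a `RunConfig` (YAML-compatible): labeled
groups of image paths or simulation spec blocks, geometry and
normalization options, α, seed, output directory.  Per-member seeds
are derived arithmetically from the run seed, so runs are reproducible
end to end; CSVs are written with a fixed float format and compare
byte-identical across reruns.  For simulated inputs the section
outline can come from the generator (`mask_source: truth`) — the
appropriate choice when the analysis under test is the profiling, as
in practice outlines come from a matched bright-field or counterstain
channel; dim fluorescence alone under-segments sections whose label
sits in the core.  Plots are conveniences; CSV/JSON are the canonical
outputs and the only ones asserted in tests.

## Problem sizes

Recovery and calibration tests run at the sizes stated above (sections
of radius 100–200 px, groups of 6 sections, 10 seeds per collagen
level, 2,000 null simulations), chosen so each guarantee is tested at
the conditions it is stated for while the whole suite stays
desk-scale.
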