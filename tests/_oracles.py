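"""Independent brute-force oracles used by the tests.

These re-implement the rim-assignment definitions with per-pixel scalar
loops (math module arithmetic, no vectorization) so that agreement with
the package's vectorized implementations is a genuine cross-check.
"""

from __future__ import annotations

import math

import numpy as np

RAY_STEP = 0.5  # must match the package's documented boundary-search step


def star_convex_labels(mask: np.ndarray, centroid: tuple[float, float],
                       n_rims: int) -> np.ndarray:
    """Scalar-loop rim assignment: boundary distance along each pixel's
    ray is the farthest multiple of RAY_STEP whose nearest pixel is in
    the mask."""
    h, w = mask.shape
    cy, cx = centroid
    ys, xs = np.nonzero(mask)
    kmax = int(np.ceil((max(math.sqrt((y - cy) ** 2 + (x - cx) ** 2)
                            for y, x in zip(ys, xs)) + 1.0) / RAY_STEP))
    labels = np.zeros(mask.shape, dtype=np.int64)
    for y, x in zip(ys, xs):
        dy, dx = y - cy, x - cx
        norm = math.sqrt(dy * dy + dx * dx)
        if norm == 0:
            labels[y, x] = 1
            continue
        uy, ux = dy / norm, dx / norm
        boundary_t = 0.0
        for k in range(kmax, 0, -1):  # farthest in-mask sample first
            t = k * RAY_STEP
            rr = math.floor(cy + t * uy + 0.5)
            cc = math.floor(cx + t * ux + 0.5)
            if 0 <= rr < h and 0 <= cc < w and mask[int(rr), int(cc)]:
                boundary_t = t
                break
        r = min(norm / max(boundary_t, RAY_STEP), 1.0)
        labels[y, x] = min(n_rims, int(math.floor(r * n_rims)) + 1)
    return labels


def circular_labels(mask: np.ndarray, centroid: tuple[float, float],
                    n_rims: int) -> np.ndarray:
    cy, cx = centroid
    r_eq = math.sqrt(mask.sum() / math.pi)
    labels = np.zeros(mask.shape, dtype=np.int64)
    for y, x in zip(*np.nonzero(mask)):
        r = min(math.sqrt((y - cy) ** 2 + (x - cx) ** 2) / r_eq, 1.0)
        labels[y, x] = min(n_rims, int(math.floor(r * n_rims)) + 1)
    return labels


def rim_means_bruteforce(pixels: np.ndarray, labels: np.ndarray,
                         n_rims: int) -> np.ndarray:
    """Per-rim mean by explicit accumulation."""
    sums = np.zeros(n_rims)
    counts = np.zeros(n_rims)
    h, w = labels.shape
    for y in range(h):
        for x in range(w):
            lab = labels[y, x]
            if lab > 0:
                sums[lab - 1] += pixels[y, x]
                counts[lab - 1] += 1
    return np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
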