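"""Independent brute-force oracles used by the test suite.

Each function re-derives an expected value from first principles, without
touching the implementation paths it is used to check.
"""

from __future__ import annotations

import numpy as np


def otsu_bruteforce(pixels: np.ndarray, n_bins: int = 256) -> float:
    """Exhaustive search over every histogram-bin split.

    Builds the equal-width histogram over the observed range, then for each
    candidate boundary computes the between-class variance directly from
    class weights and means.  Ties go to the lowest boundary.
    """
    p = np.asarray(pixels, dtype=np.float64).ravel()
    lo, hi = p.min(), p.max()
    if lo == hi:
        raise ValueError("constant image")
    hist, edges = np.histogram(p, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    best_k = None
    best_v = -np.inf
    for k in range(n_bins - 1):
        w0 = hist[: k + 1].sum()
        w1 = hist[k + 1 :].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[: k + 1] * centers[: k + 1]).sum() / w0
        mu1 = (hist[k + 1 :] * centers[k + 1 :]).sum() / w1
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_v:
            best_v = v
            best_k = k
    return float(edges[best_k + 1])


def manders_bruteforce(a: np.ndarray, b: np.ndarray, t_a: float, t_b: float):
    """Pixel-by-pixel Manders coefficients with explicit loops."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    num1 = den1 = num2 = den2 = 0.0
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            if a[i, j] > t_a:
                den1 += a[i, j]
                if b[i, j] > t_b:
                    num1 += a[i, j]
            if b[i, j] > t_b:
                den2 += b[i, j]
                if a[i, j] > t_a:
                    num2 += b[i, j]
    return num1 / den1, num2 / den2


def median_bruteforce(pixels: np.ndarray) -> np.ndarray:
    """Per-pixel median of the full 3×3 neighborhood, reflected borders."""
    p = np.pad(np.asarray(pixels), 1, mode="symmetric")
    out = np.empty_like(np.asarray(pixels))
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            out[i, j] = np.median(p[i : i + 3, j : j + 3])
    return out


def gaussian_kernel_center(sigma: float, truncate: float = 4.0) -> float:
    """Center weight of the normalized sampled 2D Gaussian kernel."""
    radius = int(truncate * sigma + 0.5)
    x = np.arange(-radius, radius + 1)
    g = np.exp(-(x**2) / (2 * sigma**2))
    g /= g.sum()
    return float(g[radius] ** 2)
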