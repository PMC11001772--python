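"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: Bessel zeros come from
bisection on a power-series evaluation, local thickness from direct
enumeration of inscribed discs in integer arithmetic, and PCA from an
explicit eigen-decomposition of the sample covariance.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# Bessel functions: power series + bisection
# ---------------------------------------------------------------------------

def bessel_j_series(m: int, x: float, terms: int = 60) -> float:
    """J_m(x) independent evaluation.

    Ascending power series for small |x|; for larger arguments the series
    loses digits to cancellation, so Bessel's integral representation
    J_m(x) = (1/pi) int_0^pi cos(m t - x sin t) dt is evaluated by
    composite Simpson quadrature instead (both routes avoid any library
    Bessel implementation).
    """
    if abs(x) < 12.0:
        total = 0.0
        for j in range(terms):
            num = (-1) ** j * (x / 2.0) ** (m + 2 * j)
            den = math.factorial(j) * math.factorial(j + m)
            total += num / den
        return total
    n = 2048  # even panel count; integrand is smooth and periodic-ish
    t = np.linspace(0.0, math.pi, n + 1)
    f = np.cos(m * t - x * np.sin(t))
    w = np.ones(n + 1)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    h = math.pi / n
    return float((h / 3.0) * (w * f).sum() / math.pi)


def bessel_zero_bisect(m: int, k: int, tol: float = 1e-12) -> float:
    """k-th positive zero of J_m by sign-change scan + bisection."""
    step = 0.1
    x = step
    found = 0
    prev = bessel_j_series(m, x)
    while True:
        x2 = x + step
        cur = bessel_j_series(m, x2)
        if prev == 0.0:
            found += 1
            if found == k:
                return x
        elif prev * cur < 0:
            found += 1
            if found == k:
                lo, hi = x, x2
                while hi - lo > tol:
                    mid = (lo + hi) / 2.0
                    if bessel_j_series(m, lo) * bessel_j_series(m, mid) <= 0:
                        hi = mid
                    else:
                        lo = mid
                return (lo + hi) / 2.0
        prev = cur
        x = x2
        if x > 60:
            raise RuntimeError("zero scan ran out of range")


# ---------------------------------------------------------------------------
# local thickness: brute-force inscribed discs (integer arithmetic)
# ---------------------------------------------------------------------------

def brute_force_local_thickness(mask: np.ndarray, pitch: float = 1.0) -> np.ndarray:
    """T(p) = max over foreground centers c of 2 * r_c * pitch where
    r_c^2 = min squared distance from c to any background pixel and
    |p - c|^2 < r_c^2 (open disc, exact integer squared distances)."""
    mask = np.asarray(mask, dtype=bool)
    nr, nc = mask.shape
    fg = np.argwhere(mask)
    bg = np.argwhere(~mask)
    out = np.zeros(mask.shape)
    if len(fg) == 0 or len(bg) == 0:
        return out
    for i, j in fg:
        d2 = int(((bg[:, 0] - i) ** 2 + (bg[:, 1] - j) ** 2).min())
        c = int(np.ceil(np.sqrt(d2)))
        ii, jj = np.meshgrid(np.arange(i - c, i + c + 1),
                             np.arange(j - c, j + c + 1), indexing="ij")
        sel = (ii - i) ** 2 + (jj - j) ** 2 < d2
        ii, jj = ii[sel], jj[sel]
        ok = (ii >= 0) & (ii < nr) & (jj >= 0) & (jj < nc)
        np.maximum.at(out, (ii[ok], jj[ok]), 2.0 * np.sqrt(d2) * pitch)
    return out


def random_blob_mask(seed: int, size: int = 64, fill: float = 0.3) -> np.ndarray:
    """Random smooth blobs for thickness-oracle comparisons."""
    from scipy import ndimage
    noise = ndimage.gaussian_filter(
        np.random.default_rng(seed).normal(size=(size, size)), 3)
    return noise > np.quantile(noise, 1.0 - fill)


# ---------------------------------------------------------------------------
# PCA: explicit eigen-decomposition of the sample covariance
# ---------------------------------------------------------------------------

def pca_eigen_oracle(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(scores, explained fractions) from eigh of the sample covariance of
    the centered samples-x-features matrix ``x``."""
    xc = x - x.mean(axis=0, keepdims=True)
    cov = xc.T @ xc / (x.shape[0] - 1)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    scores = xc @ v
    total = w.sum()
    explained = w / total if total > 0 else np.zeros_like(w)
    return scores, explained
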