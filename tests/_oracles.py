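"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by the most literal method available —
nested loops over explicit windows, exhaustive threshold scans, hand-written
ANOVA sums, Monte-Carlo sampling — sharing no code path with the package
implementation it checks.
"""

from __future__ import annotations

import numpy as np


def niblack_oracle(img: np.ndarray, radius: int, k: float) -> np.ndarray:
    """Per-pixel Niblack mask via explicit reflect-padded window loops."""
    padded = np.pad(img, radius, mode="reflect")
    out = np.zeros_like(img, dtype=bool)
    side = 2 * radius + 1
    for r in range(img.shape[0]):
        for c in range(img.shape[1]):
            win = padded[r:r + side, c:c + side]
            mu = win.mean()
            sigma = win.std()  # population SD over the window
            # dark/light rule with the tie guard: exact ties classify light
            out[r, c] = img[r, c] < mu + k * sigma - 1e-9
    return out


def bernsen_oracle(img: np.ndarray, radius: int, contrast: float,
                   low_contrast_dark: bool) -> np.ndarray:
    """Per-pixel Bernsen mask via explicit min/max windows."""
    padded = np.pad(img, radius, mode="reflect")
    out = np.zeros_like(img, dtype=bool)
    side = 2 * radius + 1
    for r in range(img.shape[0]):
        for c in range(img.shape[1]):
            win = padded[r:r + side, c:c + side]
            lo, hi = win.min(), win.max()
            if hi - lo < contrast:
                out[r, c] = low_contrast_dark
            else:
                out[r, c] = img[r, c] < (lo + hi) / 2.0
    return out


def otsu_oracle_threshold(img: np.ndarray, nbins: int = 256) -> float:
    """Exhaustive scan of all histogram splits for maximal between-class
    variance; returns the threshold as the center of the last bin of the
    dark class."""
    counts, edges = np.histogram(img.ravel(), bins=nbins, range=(img.min(), img.max()))
    centers = (edges[:-1] + edges[1:]) / 2.0
    best_var, best_i = -1.0, 0
    total = counts.sum()
    for i in range(nbins - 1):
        w0 = counts[: i + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[: i + 1] * centers[: i + 1]).sum() / w0
        mu1 = (counts[i + 1:] * centers[i + 1:]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        # first-split-wins on ties (empty bins between classes give exactly
        # equal variances; rounding noise must not flip the choice)
        if var > best_var * (1 + 1e-12):
            best_var, best_i = var, i
    return float(centers[best_i])


def anova_icc_oracle(y: np.ndarray) -> tuple[float, float, float, float]:
    """Two-way ANOVA mean squares and ICC(A,1) by explicit summation."""
    n, k = y.shape
    grand = y.sum() / (n * k)
    ss_rows = 0.0
    for i in range(n):
        ss_rows += k * (y[i].mean() - grand) ** 2
    ss_cols = 0.0
    for j in range(k):
        ss_cols += n * (y[:, j].mean() - grand) ** 2
    ss_tot = float(((y - grand) ** 2).sum())
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
    return msr, msc, mse, icc


def polygon_area_mc(vertices_rc: np.ndarray, rng: np.random.Generator,
                    n_samples: int = 1_000_000) -> float:
    """Monte-Carlo polygon area in px² via point-in-polygon ray casting."""
    r = vertices_rc[:, 0]
    c = vertices_rc[:, 1]
    r0, r1, c0, c1 = r.min(), r.max(), c.min(), c.max()
    pts_r = rng.uniform(r0, r1, n_samples)
    pts_c = rng.uniform(c0, c1, n_samples)
    inside = np.zeros(n_samples, dtype=bool)
    n = len(vertices_rc)
    for i in range(n):
        ra, ca = r[i], c[i]
        rb, cb = r[(i + 1) % n], c[(i + 1) % n]
        crosses = ((ra > pts_r) != (rb > pts_r)) & (
            pts_c < (cb - ca) * (pts_r - ra) / (rb - ra + 1e-300) + ca)
        inside ^= crosses
    return inside.mean() * (r1 - r0) * (c1 - c0)


def ols_normal_equations(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """OLS coefficients (with intercept prepended) by solving X'X b = X'y."""
    Xd = np.column_stack([np.ones(len(y)), X])
    return np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
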