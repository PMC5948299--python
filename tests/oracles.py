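"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths (and, where possible, the
libraries) they are used to check.
"""

from __future__ import annotations

import itertools

import numpy as np


def nnls_zoom_grid(A: np.ndarray, b: np.ndarray, n_levels: int = 45, n_pts: int = 13) -> np.ndarray:
    """Non-negative least squares by an exhaustive zooming tensor grid.

    Only usable for a handful of unknowns; accuracy ~box * 0.5**n_levels.
    """
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    n = A.shape[1]
    # generous upper bounds per coordinate
    hi = np.array([5.0 * abs(A[:, j] @ b) / max(A[:, j] @ A[:, j], 1e-300) + 1.0 for j in range(n)])
    lo = np.zeros(n)
    best = None
    for _ in range(n_levels):
        axes = [np.linspace(lo[j], hi[j], n_pts) for j in range(n)]
        pts = np.array(list(itertools.product(*axes)))
        r = pts @ A.T - b
        obj = (r * r).sum(axis=1)
        best = pts[int(np.argmin(obj))]
        span = (hi - lo) / (n_pts - 1) * 2.5
        lo = np.maximum(best - span, 0.0)
        hi = best + span
    return best


def two_pass_mean_sd(values, ddof: int = 1) -> tuple[float, float]:
    """Textbook two-pass mean / standard deviation."""
    v = list(float(x) for x in values)
    n = len(v)
    mean = sum(v) / n
    if n - ddof <= 0:
        return mean, float("nan")
    var = sum((x - mean) ** 2 for x in v) / (n - ddof)
    return mean, var**0.5


def two_pass_cov_percent(values) -> float:
    """Population-SD coefficient of variation in percent, two-pass."""
    v = [float(x) for x in values]
    n = len(v)
    mean = sum(v) / n
    var = sum((x - mean) ** 2 for x in v) / n
    return 100.0 * var**0.5 / mean


def wilcoxon_exact_enumeration(pairs) -> tuple[float, float]:
    """Exact two-sided signed-rank p by full 2^n sign enumeration.

    Differences must be non-zero and have distinct absolute values.
    """
    d = np.array([a - b for a, b in pairs], dtype=float)
    d = d[d != 0]
    n = len(d)
    order = np.argsort(np.abs(d))
    ranks = np.empty(n)
    ranks[order] = np.arange(1, n + 1)
    w_pos = ranks[d > 0].sum()
    w_neg = ranks[d < 0].sum()
    w_lo, w_hi = min(w_pos, w_neg), max(w_pos, w_neg)
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        t_pos = sum(r for r, s in zip(ranks, signs) if s)
        if t_pos <= w_lo or t_pos >= w_hi:
            count += 1
    return float(w_lo), count / 2.0**n
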