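"""Independent brute-force oracles used to check the implementation.

These deliberately avoid the code paths they verify: the monotone fit is
found by exhaustive enumeration of contiguous block partitions, tail
precisions by O(n^2) pairwise counting, and curve inversion by dense grid
scanning.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def exhaustive_isotonic(x, y, w):
    """Weighted least-squares monotone (non-decreasing) fit on distinct x.

    Enumerates all contiguous partitions of the knots into blocks, assigns
    each block its weighted mean, keeps partitions whose block means are
    non-decreasing, and returns the feasible fit with minimal weighted SSE.
    Exponential: only for small m.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    m = len(x)
    assert np.all(np.diff(x) > 0)
    best_sse, best_fit = np.inf, None
    for n_cuts in range(m):
        for cuts in combinations(range(1, m), n_cuts):
            bounds = [0, *cuts, m]
            fit = np.empty(m)
            means = []
            for lo, hi in zip(bounds[:-1], bounds[1:]):
                mu = np.average(y[lo:hi], weights=w[lo:hi])
                means.append(mu)
                fit[lo:hi] = mu
            if np.any(np.diff(means) < -1e-12):
                continue
            sse = float(np.sum(w * (y - fit) ** 2))
            if sse < best_sse - 1e-15:
                best_sse, best_fit = sse, fit
    return best_fit


def brute_tail_precision(scores, correct):
    """Pindex(score_i) by direct pairwise counting."""
    scores = np.asarray(scores, float)
    correct = np.asarray(correct, bool)
    out = np.empty(len(scores))
    for i, a in enumerate(scores):
        mask = scores >= a
        out[i] = correct[mask].mean()
    return out


def brute_rp_points(scores, correct, thresholds, n_total):
    """Raw P(a), R(a) at given thresholds by direct subset counting."""
    scores = np.asarray(scores, float)
    correct = np.asarray(correct, bool)
    P, R = [], []
    for a in thresholds:
        mask = scores >= a
        n_corr = int(correct[mask].sum())
        P.append(n_corr / mask.sum() if mask.any() else np.nan)
        R.append(n_corr / n_total)
    return np.array(P), np.array(R)


def grid_inverse_precision(curve, P0, resolution=1e-4):
    """Smallest grid threshold with smoothed precision >= P0."""
    lo, hi = curve.thresholds[0], curve.thresholds[-1]
    grid = np.arange(0.0, hi + resolution, resolution)
    p = curve.precision_at(grid)
    ok = np.flatnonzero(p >= P0)
    return None if ok.size == 0 else float(grid[ok[0]])


def grid_inverse_recall(curve, R0, resolution=1e-4):
    """Largest grid threshold with smoothed recall >= R0."""
    hi = curve.thresholds[-1]
    grid = np.arange(0.0, hi + resolution, resolution)
    r = curve.recall_at(grid)
    ok = np.flatnonzero(r >= R0)
    return None if ok.size == 0 else float(grid[ok[-1]])
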