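"""Compiled inner loops for the nonlinear time-series features.

Recurrence line statistics, sample-entropy template counting and the
nearest-neighbour divergence curve are all O(n^2) in the signal length;
they are JIT-compiled so that a full three-sensor session stays well under
the per-session runtime target.  The public modules keep pure-NumPy matrix
paths for small inputs and testing; equivalence of the two paths is
asserted in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def rqa_counts(emb: np.ndarray, eps: float, theiler: int):
    """Recurrence statistics straight from the embedded trajectory.

    Returns ``(n_recurrent, diag_hist, vert_hist)`` where ``n_recurrent``
    counts all matrix entries with distance <= eps (including the main
    diagonal), ``diag_hist[l]`` counts diagonal lines of length ``l`` over
    offsets ``|k| > theiler`` and ``vert_hist[l]`` counts vertical lines
    over full columns of the (implicit) recurrence matrix.
    """
    n, m = emb.shape
    eps2 = eps * eps
    diag_hist = np.zeros(n + 1, dtype=np.int64)
    vert_hist = np.zeros(n + 1, dtype=np.int64)
    n_recurrent = n  # main diagonal

    # diagonal lines: walk each offset k >= 1; symmetry doubles the counts
    for k in range(1, n):
        run = 0
        count_lines = k > theiler
        for i in range(n - k):
            d2 = 0.0
            for j in range(m):
                diff = emb[i, j] - emb[i + k, j]
                d2 += diff * diff
            if d2 <= eps2:
                n_recurrent += 2
                run += 1
            else:
                if run > 0 and count_lines:
                    diag_hist[run] += 2
                run = 0
        if run > 0 and count_lines:
            diag_hist[run] += 2

    # vertical lines: walk each column of the full matrix
    for j in range(n):
        run = 0
        for i in range(n):
            if i == j:
                recurrent = True
            else:
                d2 = 0.0
                for c in range(m):
                    diff = emb[i, c] - emb[j, c]
                    d2 += diff * diff
                recurrent = d2 <= eps2
            if recurrent:
                run += 1
            else:
                if run > 0:
                    vert_hist[run] += 1
                run = 0
        if run > 0:
            vert_hist[run] += 1

    return n_recurrent, diag_hist, vert_hist


@njit(cache=False)
def sampen_counts(sig: np.ndarray, m: int, r: float):
    """Chebyshev template-match counts for sample entropy.

    Counts pairs (i < j) among the ``n - m`` templates whose first ``m``
    points match within ``r`` (B) and whose ``m + 1`` points match (A);
    self-matches are excluded by construction.
    """
    n = sig.shape[0]
    n_templates = n - m
    b_count = 0
    a_count = 0
    for i in range(n_templates - 1):
        for j in range(i + 1, n_templates):
            match = True
            for k in range(m):
                if abs(sig[i + k] - sig[j + k]) > r:
                    match = False
                    break
            if match:
                b_count += 1
                if abs(sig[i + m] - sig[j + m]) <= r:
                    a_count += 1
    return b_count, a_count


@njit(cache=False)
def nn_divergence(emb: np.ndarray, theiler: int, max_k: int):
    """Rosenstein mean log-divergence curve.

    For each trajectory point the nearest neighbour at temporal distance
    > ``theiler`` is found by brute force; the curve value at step ``k`` is
    the mean natural log of the pair separations after ``k`` steps, over
    pairs still inside the series.  Zero separations are skipped.
    """
    n, m = emb.shape
    nn = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        best = np.inf
        best_j = -1
        for j in range(n):
            if abs(i - j) <= theiler:
                continue
            d2 = 0.0
            for c in range(m):
                diff = emb[i, c] - emb[j, c]
                d2 += diff * diff
            if d2 < best:
                best = d2
                best_j = j
        nn[i] = best_j

    curve = np.full(max_k + 1, np.nan)
    for k in range(max_k + 1):
        total = 0.0
        count = 0
        for i in range(n):
            j = nn[i]
            if j < 0 or i + k >= n or j + k >= n:
                continue
            d2 = 0.0
            for c in range(m):
                diff = emb[i + k, c] - emb[j + k, c]
                d2 += diff * diff
            if d2 > 0.0:
                total += 0.5 * np.log(d2)
                count += 1
        if count > 0:
            curve[k] = total / count
    return curve
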