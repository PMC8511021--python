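"""Inner loops for pattern-vs-window edit-distance scoring.

The hot path computes, for every pattern in a 9^n (or repeat-free) space
and every length-n window of a sequence, the optimal-string-alignment
Damerau-Levenshtein distance, and accumulates 1/(d+1) terms.  A numba
version is used when available; a vectorised NumPy fallback covers the
same contract and is checked against it in the tests.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly on import
    import numba

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    numba = None
    HAVE_NUMBA = False


def _score_kernel_py(patterns, windows, counts, inv_table, out):
    """Reference loop: OSA DP per (pattern, window), accumulate count/(d+1)."""
    n_pat, n = patterns.shape
    n_win, m = windows.shape
    d = np.empty((n + 1, m + 1), dtype=np.int64)
    for p in range(n_pat):
        pat = patterns[p]
        acc = 0.0
        for w in range(n_win):
            win = windows[w]
            for i in range(n + 1):
                d[i, 0] = i
            for j in range(m + 1):
                d[0, j] = j
            for i in range(1, n + 1):
                for j in range(1, m + 1):
                    cost = 0 if pat[i - 1] == win[j - 1] else 1
                    best = d[i - 1, j - 1] + cost
                    if d[i - 1, j] + 1 < best:
                        best = d[i - 1, j] + 1
                    if d[i, j - 1] + 1 < best:
                        best = d[i, j - 1] + 1
                    if (
                        i > 1
                        and j > 1
                        and pat[i - 1] == win[j - 2]
                        and pat[i - 2] == win[j - 1]
                        and d[i - 2, j - 2] + 1 < best
                    ):
                        best = d[i - 2, j - 2] + 1
                    d[i, j] = best
            acc += counts[w] * inv_table[d[n, m]]
        out[p] = acc


if HAVE_NUMBA:
    _score_kernel_numba = numba.njit(cache=False, fastmath=False)(_score_kernel_py)


def _score_kernel_numpy(patterns, windows, counts, inv_table, out):
    """Same contract, DP vectorised across all (pattern, window) pairs.

    Rows of the DP table are (m+1, n_pat, n_win) arrays; only the last
    three rows are retained, so the cell loop is (n+1)*(m+1) long and the
    per-cell work is pure array arithmetic over all pairs at once.
    """
    n_pat, n = patterns.shape
    n_win, m = windows.shape
    pat = patterns.astype(np.int16)
    win = windows.astype(np.int16)
    shape = (m + 1, n_pat, n_win)
    row_prev2 = None
    row_prev = np.empty(shape, dtype=np.int16)
    for j in range(m + 1):
        row_prev[j] = j
    for i in range(1, n + 1):
        row_cur = np.empty(shape, dtype=np.int16)
        row_cur[0] = i
        for j in range(1, m + 1):
            cost = (pat[:, i - 1, None] != win[None, :, j - 1]).astype(np.int16)
            best = row_prev[j - 1] + cost
            np.minimum(best, row_prev[j] + 1, out=best)
            np.minimum(best, row_cur[j - 1] + 1, out=best)
            if i > 1 and j > 1:
                trans = (pat[:, i - 1, None] == win[None, :, j - 2]) & (
                    pat[:, i - 2, None] == win[None, :, j - 1]
                )
                alt = row_prev2[j - 2] + 1
                best = np.where(trans & (alt < best), alt, best)
            row_cur[j] = best
        row_prev2, row_prev = row_prev, row_cur
    final = row_prev[m]
    out[:] = (inv_table[final] * counts[None, :]).sum(axis=1)


def score_all_patterns(
    patterns: np.ndarray, windows: np.ndarray, counts: np.ndarray
) -> np.ndarray:
    """Sum of counts/(OSA distance + 1) per pattern over the given windows.

    Parameters
    ----------
    patterns : (P, n) int array
    windows : (W, m) int array of distinct windows
    counts : (W,) float array of window multiplicities
    """
    patterns = np.ascontiguousarray(patterns, dtype=np.int8)
    windows = np.ascontiguousarray(windows, dtype=np.int8)
    counts = np.ascontiguousarray(counts, dtype=np.float64)
    n, m = patterns.shape[1], windows.shape[1]
    inv_table = 1.0 / (1.0 + np.arange(max(n, m) + 1, dtype=np.float64))
    out = np.empty(patterns.shape[0], dtype=np.float64)
    if HAVE_NUMBA:
        _score_kernel_numba(patterns, windows, counts, inv_table, out)
    else:
        _score_kernel_numpy(patterns, windows, counts, inv_table, out)
    return out
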