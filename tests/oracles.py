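"""Independent oracles used by the tests.

Everything here is deliberately written without reference to the package
internals: a memoized *recursive* optimal-string-alignment edit distance,
a brute-force AUC by exhaustive pair counting, and a closed-form
jackknife SE for the sample mean.
"""

from __future__ import annotations

import functools
import math


def osa_recursive(a: tuple[int, ...], b: tuple[int, ...]) -> int:
    """Recursive OSA Damerau-Levenshtein distance (memoized brute force)."""

    @functools.lru_cache(maxsize=None)
    def d(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        cost = 0 if a[i - 1] == b[j - 1] else 1
        best = min(d(i - 1, j) + 1, d(i, j - 1) + 1, d(i - 1, j - 1) + cost)
        if i > 1 and j > 1 and a[i - 1] == b[j - 2] and a[i - 2] == b[j - 1]:
            best = min(best, d(i - 2, j - 2) + 1)
        return best

    return d(len(a), len(b))


def brute_force_auc(match: list[float], non_match: list[float]) -> float:
    """P(match < non-match) + 0.5 P(tie) by exhaustive double loop."""
    wins = 0.0
    for dm in match:
        for dn in non_match:
            if dm < dn:
                wins += 1.0
            elif dm == dn:
                wins += 0.5
    return wins / (len(match) * len(non_match))


def jackknife_se_mean(values: list[float]) -> float:
    """Closed-form jackknife SE of the sample mean: sqrt(S^2 / n) with ddof=1."""
    n = len(values)
    mean = sum(values) / n
    s2 = sum((v - mean) ** 2 for v in values) / (n - 1)
    return math.sqrt(s2 / n)
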