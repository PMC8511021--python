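"""Variation-tolerant pattern-prevalence scoring of digit sequences.

The central statistic is the Damerau-Levenshtein score (DLS) of a pattern
m on a sequence z: the pattern is slid over every position of the
sequence, the edit distance between the pattern and each length-|m|
window is computed, and the terms 1/(distance + 1) are summed and
divided by the sequence length L,

    s(m, z) = (1/L) * sum_w 1 / (d_OSA(m, w) + 1),

so exact occurrences contribute 1 and near-misses contribute fractions.
The edit distance is the optimal-string-alignment (OSA) variant of the
Damerau-Levenshtein distance: unit-cost insertions, deletions,
substitutions and adjacent transpositions, with each element taking part
in at most one transposition.

An exact-match counterpart (windows matching the pattern verbatim,
divided by L) serves as the tolerance-free baseline.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

from ._kernels import score_all_patterns
from .corpus import Corpus, DigitSequence

__all__ = [
    "Pattern",
    "PatternSpace",
    "dl_distance",
    "enumerate_patterns",
    "pattern_score",
    "exact_pattern_count",
    "score_vector",
    "exact_count_vector",
    "score_matrix",
    "write_score_matrix",
]

MAX_PATTERN_LENGTH = 6

Pattern = tuple[int, ...]


def dl_distance(a: Sequence[int] | str, b: Sequence[int] | str) -> int:
    """Optimal-string-alignment Damerau-Levenshtein distance.

    Counts the minimum number of unit-cost insertions, deletions,
    substitutions and transpositions of adjacent elements converting
    ``a`` into ``b``, under the OSA restriction that no element is
    edited after taking part in a transposition.  Accepts digit strings
    or integer sequences; total on its domain, symmetric, and zero
    exactly for equal inputs.
    """
    x = [int(c) for c in a]
    y = [int(c) for c in b]
    n, m = len(x), len(y)
    if n == 0:
        return m
    if m == 0:
        return n
    prev2: list[int] | None = None
    prev = list(range(m + 1))
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        xi = x[i - 1]
        for j in range(1, m + 1):
            cost = 0 if xi == y[j - 1] else 1
            best = min(prev[j - 1] + cost, prev[j] + 1, cur[j - 1] + 1)
            if i > 1 and j > 1 and xi == y[j - 2] and x[i - 2] == y[j - 1]:
                best = min(best, prev2[j - 2] + 1)
            cur[j] = best
        prev2, prev = prev, cur
    return prev[m]


@dataclass(frozen=True)
class PatternSpace:
    """The enumerated space of length-n digit patterns in lexicographic order.

    With ``exclude_repeats`` the patterns containing any adjacent equal
    digits (e.g. (1,1,5)) are removed, leaving 9*8^(n-1) of the 9^n
    patterns.  Enumeration order is lexicographic and deterministic.
    """

    n: int
    exclude_repeats: bool
    patterns: tuple[Pattern, ...]

    def __len__(self) -> int:
        return len(self.patterns)

    @property
    def labels(self) -> list[str]:
        return ["".join(map(str, p)) for p in self.patterns]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.patterns, dtype=np.int8)

    def index_of(self, pattern: Pattern) -> int:
        return self.patterns.index(tuple(int(d) for d in pattern))


def enumerate_patterns(n: int, exclude_repeats: bool = False) -> PatternSpace:
    """Enumerate all length-``n`` digit patterns over 1..9, lexicographically."""
    if not 1 <= n <= MAX_PATTERN_LENGTH:
        raise ValueError(f"pattern length must be in 1..{MAX_PATTERN_LENGTH}, got {n}")
    pats: Iterable[Pattern] = itertools.product(range(1, 10), repeat=n)
    if exclude_repeats:
        pats = (
            p for p in pats if all(p[i] != p[i + 1] for i in range(n - 1))
        )
    return PatternSpace(n=n, exclude_repeats=exclude_repeats, patterns=tuple(pats))


def _digits_of(z: DigitSequence | Sequence[int]) -> np.ndarray:
    if isinstance(z, DigitSequence):
        return z.as_array()
    return np.asarray(list(z), dtype=np.int8)


def _windows(digits: np.ndarray, n: int) -> np.ndarray:
    L = len(digits)
    if n > L:
        raise ValueError(f"pattern length {n} exceeds sequence length {L}")
    return np.lib.stride_tricks.sliding_window_view(digits, n)


def pattern_score(m: Sequence[int], z: DigitSequence | Sequence[int]) -> float:
    """DLS prevalence of a single pattern on a sequence.

    Sums 1/(d+1) over all full-length windows (positions 1 .. L-|m|+1)
    and divides by the sequence length L.
    """
    digits = _digits_of(z)
    mm = [int(d) for d in m]
    wins = _windows(digits, len(mm))
    total = sum(1.0 / (dl_distance(mm, w.tolist()) + 1) for w in wins)
    return total / len(digits)


def exact_pattern_count(m: Sequence[int], z: DigitSequence | Sequence[int]) -> float:
    """Exact-match prevalence: (# windows equal to the pattern) / L."""
    digits = _digits_of(z)
    mm = np.asarray([int(d) for d in m], dtype=np.int8)
    wins = _windows(digits, len(mm))
    return float((wins == mm).all(axis=1).sum()) / len(digits)


def score_vector(z: DigitSequence | Sequence[int], space: PatternSpace) -> np.ndarray:
    """DLS score of every pattern in ``space`` on sequence ``z``.

    Equivalent to ``[pattern_score(m, z) for m in space.patterns]`` but
    computed through a shared kernel over the distinct windows of the
    sequence (windows repeat, so distances are computed once per
    distinct window and weighted by multiplicity).
    """
    digits = _digits_of(z)
    wins = _windows(digits, space.n)
    uniq, counts = np.unique(wins, axis=0, return_counts=True)
    sums = score_all_patterns(space.as_array(), uniq, counts.astype(float))
    return sums / len(digits)


def exact_count_vector(
    z: DigitSequence | Sequence[int], space: PatternSpace
) -> np.ndarray:
    """Exact-match counterpart of :func:`score_vector` (non-DLS baseline)."""
    digits = _digits_of(z)
    wins = _windows(digits, space.n)
    uniq, counts = np.unique(wins, axis=0, return_counts=True)
    # map each distinct window to its lexicographic index, then gather
    lut = {tuple(int(d) for d in u): c for u, c in zip(uniq, counts)}
    values = np.array([lut.get(p, 0) for p in space.patterns], dtype=float)
    return values / len(digits)


def score_matrix(
    corpus: Corpus | Iterable[DigitSequence],
    space: PatternSpace,
    method: str = "dls",
) -> pd.DataFrame:
    """Score every sequence of a corpus against a pattern space.

    Returns a DataFrame indexed by (subject_id, session) with one column
    per pattern (header = concatenated digits), in the space's
    lexicographic order.  ``method`` selects the variation-tolerant DLS
    scores ('dls') or the exact-match counts ('exact').
    """
    if method not in ("dls", "exact"):
        raise ValueError(f"unknown scoring method {method!r}")
    fn = score_vector if method == "dls" else exact_count_vector
    keys, rows = [], []
    for seq in corpus:
        keys.append(seq.key)
        rows.append(fn(seq, space))
    idx = pd.MultiIndex.from_tuples(keys, names=["subject_id", "session"])
    return pd.DataFrame(np.vstack(rows), index=idx, columns=space.labels)


def write_score_matrix(scores: pd.DataFrame, path: str | Path) -> None:
    scores.to_csv(path, sep="\t")
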