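"""Corpus-level score standardization and the robust inter-sequence distance.

Each pattern's scores are z-scored across the sequences entering the
analysis (population SD; zero-variance patterns map to zero).  The
distance between two sequences over a length-n pattern space is then

    d_n(z1, z2) = sqrt( sum_i tanh^2( s_i(z1) - s_i(z2) ) )

on the standardized scores; the tanh damping caps each pattern's
contribution below 1 so a few large strategy shifts cannot dominate the
aggregate.  The plain Euclidean norm ("native" form) is available for
comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StandardizedScores",
    "standardize_scores",
    "dls_distance",
    "pairwise_distances",
]


@dataclass
class StandardizedScores:
    """Column-standardized score matrix with the moments used."""

    matrix: pd.DataFrame  # (subject_id, session) x pattern, z-scored
    mean: np.ndarray
    sd: np.ndarray

    @property
    def n_patterns(self) -> int:
        return self.matrix.shape[1]


def standardize_scores(raw: pd.DataFrame) -> StandardizedScores:
    """Z-score each pattern column over all sequences (population SD).

    Columns with zero raw standard deviation become all-zero, so
    patterns used identically by everyone carry no distance.
    """
    if raw.shape[0] < 2:
        raise ValueError("standardization needs at least 2 sequences")
    values = raw.to_numpy(dtype=float)
    mean = values.mean(axis=0)
    sd = values.std(axis=0)  # population (ddof=0)
    safe = np.where(sd > 0, sd, 1.0)
    z = (values - mean) / safe
    z[:, sd == 0] = 0.0
    return StandardizedScores(
        matrix=pd.DataFrame(z, index=raw.index, columns=raw.columns),
        mean=mean,
        sd=sd,
    )


def dls_distance(u: np.ndarray, v: np.ndarray, robust: bool = True) -> float:
    """Distance between two standardized score vectors.

    robust=True: sqrt(sum tanh^2(u_i - v_i)); robust=False: Euclidean norm.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    diff = u - v
    if robust:
        diff = np.tanh(diff)
    return float(np.sqrt((diff * diff).sum()))


def pairwise_distances(
    std: StandardizedScores,
    pairing: tuple[int, int] = (1, 2),
    robust: bool = True,
    scheme: str = "cross-session",
) -> pd.DataFrame:
    """Distances for all cross-session sequence pairs, labelled match/non-match.

    With the default 'cross-session' scheme, every session-``pairing[0]``
    sequence is paired with every session-``pairing[1]`` sequence of a
    different or the same subject; the pair is a *match* when both come
    from the same subject.  Subjects lacking either session are skipped
    with a warning.  The 'all-pairs' scheme instead pairs every sequence
    with every other sequence regardless of session.

    Returns a DataFrame with columns subject_a, session_a, subject_b,
    session_b, distance, label.
    """
    m = std.matrix
    rows = []
    if scheme == "cross-session":
        sa, sb = pairing
        idx = m.index
        subs_a = {s for s, sess in idx if sess == sa}
        subs_b = {s for s, sess in idx if sess == sb}
        usable = sorted(subs_a & subs_b)
        skipped = sorted((subs_a | subs_b) - set(usable))
        if skipped:
            warnings.warn(
                f"subjects lacking session {sa} or {sb} skipped from pairing: {skipped}",
                stacklevel=2,
            )
        va = m.loc[[(s, sa) for s in usable]].to_numpy()
        vb = m.loc[[(s, sb) for s in usable]].to_numpy()
        diff = va[:, None, :] - vb[None, :, :]
        if robust:
            diff = np.tanh(diff)
        dmat = np.sqrt((diff * diff).sum(axis=2))
        for i, s1 in enumerate(usable):
            for j, s2 in enumerate(usable):
                rows.append(
                    (s1, sa, s2, sb, dmat[i, j], "match" if s1 == s2 else "non_match")
                )
    elif scheme == "all-pairs":
        keys = list(m.index)
        vals = m.to_numpy()
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                d = dls_distance(vals[i], vals[j], robust=robust)
                label = "match" if keys[i][0] == keys[j][0] else "non_match"
                rows.append((*keys[i], *keys[j], d, label))
    else:
        raise ValueError(f"unknown pairing scheme {scheme!r}")
    return pd.DataFrame(
        rows,
        columns=["subject_a", "session_a", "subject_b", "session_b", "distance", "label"],
    )
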