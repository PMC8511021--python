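"""Same-author identification from pair distances: ROC/AUC and jackknife tests.

A pair of sequences is classified as *match* (same author) when its
distance falls below a threshold.  Sweeping the threshold yields the
ROC; the area under it is computed in its Mann-Whitney rank form — the
probability that a randomly chosen match pair lies closer than a
randomly chosen non-match pair, ties counting one half — which equals
the trapezoidal area under the full ROC.

Inference is by leave-one-subject-out jackknife: each replicate removes
one subject entirely and recomputes standardization, pairing and AUC, so
the dependence between pairs sharing a subject is respected.  The trend
of AUC across pattern lengths and differences between two analyses are
tested with jackknife z statistics against the normal distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .corpus import Corpus
from .distance import pairwise_distances, standardize_scores
from .scoring import enumerate_patterns, score_matrix

__all__ = [
    "ROCResult",
    "TestResult",
    "roc_auc",
    "auc_from_pairs",
    "jackknife_se",
    "identification_analysis",
    "jackknife_auc",
    "trend_test",
    "difference_test",
    "IdentificationResult",
]


@dataclass
class ROCResult:
    """AUC with the full set of ROC operating points."""

    auc: float
    n_match: int
    n_non_match: int
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    jackknife_se: float | None = None


@dataclass
class TestResult:
    """A jackknife z test: statistic, two- or one-tailed p, estimate, SE."""

    z: float
    p: float
    estimate: float
    se: float
    flag: str | None = None


def roc_auc(match: Sequence[float], non_match: Sequence[float]) -> ROCResult:
    """AUC and ROC points for distance-based match/non-match classification.

    Smaller distance means match.  AUC is the Mann-Whitney statistic
    P(d_match < d_non_match) + 0.5 P(tie).
    """
    dm = np.asarray(match, dtype=float)
    dn = np.asarray(non_match, dtype=float)
    if len(dm) == 0 or len(dn) == 0:
        raise ValueError("need at least one match and one non-match pair")
    pooled = np.concatenate([dm, dn])
    ranks = stats.rankdata(pooled)
    r_match = ranks[: len(dm)].sum()
    # pairs in which the match distance exceeds the non-match distance (+ half ties)
    u_greater = r_match - len(dm) * (len(dm) + 1) / 2.0
    auc = 1.0 - u_greater / (len(dm) * len(dn))

    thresholds = np.unique(pooled)
    # predict match when distance <= threshold
    tpr = np.array([(dm <= t).mean() for t in thresholds])
    fpr = np.array([(dn <= t).mean() for t in thresholds])
    return ROCResult(
        auc=float(auc),
        n_match=len(dm),
        n_non_match=len(dn),
        thresholds=thresholds,
        tpr=tpr,
        fpr=fpr,
    )


def auc_from_pairs(pairs: pd.DataFrame) -> ROCResult:
    """AUC from a pair-distance table (columns ``distance`` and ``label``)."""
    dm = pairs.loc[pairs["label"] == "match", "distance"].to_numpy()
    dn = pairs.loc[pairs["label"] == "non_match", "distance"].to_numpy()
    return roc_auc(dm, dn)


def jackknife_se(replicates: Sequence[float]) -> float:
    """Jackknife standard error sqrt((n-1)/n * sum (theta_i - mean)^2)."""
    th = np.asarray(replicates, dtype=float)
    n = len(th)
    if n < 2:
        raise ValueError("need at least 2 jackknife replicates")
    return float(np.sqrt((n - 1) / n * ((th - th.mean()) ** 2).sum()))


@dataclass
class IdentificationResult:
    """Per-length identification performance and jackknife replicates."""

    summary: pd.DataFrame  # index n, columns auc, se, n_match, n_non_match
    replicates: pd.DataFrame | None  # left-out subject x pattern length
    roc: dict[int, ROCResult] = field(default_factory=dict)


def _auc_for_scores(
    raw_by_length: Mapping[int, pd.DataFrame],
    pairing: tuple[int, int],
    robust: bool,
) -> dict[int, ROCResult]:
    out = {}
    for n, raw in raw_by_length.items():
        std = standardize_scores(raw)
        pairs = pairwise_distances(std, pairing=pairing, robust=robust)
        out[n] = auc_from_pairs(pairs)
    return out


def identification_analysis(
    corpus: Corpus,
    lengths: Iterable[int] = (1, 2, 3, 4, 5, 6),
    method: str = "dls",
    exclude_repeats: bool = True,
    pairing: tuple[int, int] = (1, 2),
    robust: bool = True,
    jackknife: bool = False,
) -> IdentificationResult:
    """Full identification pipeline: score, standardize, pair, AUC per length.

    Only sequences from the two paired sessions enter the analysis (and
    its standardization population).  ``method`` is 'dls' or 'exact';
    pattern spaces exclude adjacent-repeat patterns by default.  With
    ``jackknife=True``, leave-one-subject-out replicates recompute the
    standardization, pairing and AUC, giving standard errors.
    """
    lengths = list(lengths)
    wanted = set(pairing)
    sub = Corpus(sequences=[s for s in corpus if s.session in wanted])
    raw_by_length: dict[int, pd.DataFrame] = {}
    for n in lengths:
        space = enumerate_patterns(n, exclude_repeats=exclude_repeats)
        raw_by_length[n] = score_matrix(sub, space, method=method)

    roc = _auc_for_scores(raw_by_length, pairing, robust)

    replicates = None
    se: dict[int, float | None] = {n: None for n in lengths}
    if jackknife:
        subjects = sorted(
            {s for s, sess in raw_by_length[lengths[0]].index if sess == pairing[0]}
            & {s for s, sess in raw_by_length[lengths[0]].index if sess == pairing[1]}
        )
        if len(subjects) < 3:
            raise ValueError("jackknife needs at least 3 subjects")
        rows = []
        for left_out in subjects:
            rep = {}
            for n in lengths:
                raw = raw_by_length[n]
                mask = raw.index.get_level_values("subject_id") != left_out
                rep[n] = _auc_for_scores({n: raw[mask]}, pairing, robust)[n].auc
            rows.append(rep)
        replicates = pd.DataFrame(rows, index=pd.Index(subjects, name="left_out"))
        for n in lengths:
            se[n] = jackknife_se(replicates[n].to_numpy())
            roc[n].jackknife_se = se[n]

    summary = pd.DataFrame(
        {
            "auc": [roc[n].auc for n in lengths],
            "se": [se[n] for n in lengths],
            "n_match": [roc[n].n_match for n in lengths],
            "n_non_match": [roc[n].n_non_match for n in lengths],
        },
        index=pd.Index(lengths, name="n"),
    )
    return IdentificationResult(summary=summary, replicates=replicates, roc=roc)


def jackknife_auc(
    corpus: Corpus,
    length: int,
    **kwargs,
) -> tuple[float, float]:
    """Convenience wrapper: (AUC, jackknife SE) at one pattern length."""
    res = identification_analysis(corpus, lengths=[length], jackknife=True, **kwargs)
    row = res.summary.loc[length]
    return float(row["auc"]), float(row["se"])


def _z_to_p(z: float, tail: str) -> float:
    if tail == "two":
        return float(2.0 * stats.norm.sf(abs(z)))
    if tail == "one":
        return float(stats.norm.sf(z))
    raise ValueError(f"tail must be 'one' or 'two', got {tail!r}")


def trend_test(replicates: pd.DataFrame, tail: str = "two") -> TestResult:
    """Jackknife test of a linear trend of AUC across pattern lengths.

    ``replicates``: one row per jackknife replicate, one column per
    pattern length (column labels are the numeric lengths).  Each
    replicate's AUCs are regressed on length by ordinary least squares;
    z = mean slope / jackknife SE of the slope.
    """
    lengths = np.asarray(replicates.columns, dtype=float)
    if len(lengths) < 2:
        raise ValueError("trend test needs at least 2 pattern lengths")
    if len(replicates) < 3:
        raise ValueError("trend test needs at least 3 jackknife replicates")
    slopes = np.array(
        [np.polyfit(lengths, row.to_numpy(dtype=float), 1)[0] for _, row in replicates.iterrows()]
    )
    mean_slope = float(slopes.mean())
    se = jackknife_se(slopes)
    eps = 1e-12
    if se <= eps:
        if abs(mean_slope) <= eps:
            return TestResult(z=0.0, p=1.0, estimate=0.0, se=se, flag="zero-slope")
        z = math.inf if mean_slope > 0 else -math.inf
        return TestResult(z=z, p=0.0, estimate=mean_slope, se=se, flag="zero-variance")
    z = mean_slope / se
    return TestResult(z=float(z), p=_z_to_p(z, tail), estimate=mean_slope, se=se)


def difference_test(
    auc_a: Sequence[float],
    auc_b: Sequence[float],
    tail: str = "two",
) -> TestResult:
    """Jackknife test of a difference between two aligned replicate sets.

    Replicates must be aligned (same left-out subject per position);
    z = mean(a - b) / jackknife SE of (a - b).  One-tailed tests the
    alternative mean(a) > mean(b).
    """
    a = np.asarray(auc_a, dtype=float)
    b = np.asarray(auc_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("replicate sets must be aligned and equal length")
    if isinstance(auc_a, pd.Series) and isinstance(auc_b, pd.Series):
        if not auc_a.index.equals(auc_b.index):
            raise ValueError("replicate indices (left-out subjects) are misaligned")
    delta = a - b
    mean_d = float(delta.mean())
    se = jackknife_se(delta)
    if se == 0.0:
        if mean_d == 0.0:
            p = 1.0 if tail == "two" else 0.5
            return TestResult(z=0.0, p=p, estimate=0.0, se=0.0, flag="zero-difference")
        z = math.inf if mean_d > 0 else -math.inf
        return TestResult(z=z, p=0.0 if z > 0 or tail == "two" else 1.0,
                          estimate=mean_d, se=0.0, flag="zero-variance")
    z = mean_d / se
    return TestResult(z=float(z), p=_z_to_p(z, tail), estimate=mean_d, se=se)
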