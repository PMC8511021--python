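"""Pattern preference/inhibition individuality analysis.

For each subject, patterns are ordered from the subject's most inhibited
(rarest, ordinal 1) to most preferred (ordinal 9^n) by their prevalence
scores in the first session, over the FULL pattern space including
adjacent repeats.  At each ordinal the subject's rank-k pattern is
compared between

* her own two sessions (within-subject difference), and
* her first session and all other subjects' first sessions
  (between-subject difference),

both as absolute score differences.  The gap delta = between - within is
the degree of individuality carried by patterns of that prevalence rank:
elevated delta at the top ordinals signals person-specific preferences,
at the bottom ordinals person-specific inhibitions.

The ordinal axis is split into named bands (universal exceptions, rare
duplets, rare x-y-x patterns, individual inhibitions, individual
preferences); the most frequent band members across subjects, and a test
of whether each subject's familiar numbers (birthdates, phone numbers,
postal codes) are over- or under-represented in her own sequence, round
out the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import PatternSpace

__all__ = [
    "IndividualityCurve",
    "BandSpec",
    "default_bands",
    "ordinal_ranks",
    "individuality_curve",
    "band_top_patterns",
    "data_driven_bands",
    "familiar_subpatterns",
    "familiar_pattern_test",
    "FamiliarTestResult",
]


@dataclass
class IndividualityCurve:
    """Mean within/between differences and their gap, per prevalence ordinal."""

    n: int
    table: pd.DataFrame  # index ordinal 1..9^n; columns within, between,
    # within_se, between_se, delta, delta_se
    n_subjects: int = 0

    @property
    def delta(self) -> np.ndarray:
        return self.table["delta"].to_numpy()


@dataclass(frozen=True)
class BandSpec:
    """Named inclusive ordinal ranges on the prevalence axis."""

    bands: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        names = [b[0] for b in self.bands]
        if len(names) != len(set(names)):
            raise ValueError("band names must be unique")
        for name, lo, hi in self.bands:
            if lo < 1 or hi < lo:
                raise ValueError(f"invalid band range for {name!r}: [{lo}, {hi}]")


def default_bands(n_patterns: int = 729) -> BandSpec:
    """The standard five bands on the length-3 ordinal scale.

    For 729 patterns the canonical ranges are used verbatim (note the
    deliberate overlap at ordinal 230 and the unassigned 301-699 region);
    other space sizes get the same bands scaled proportionally.
    """
    canonical = (
        ("universal_exceptions", 1, 10),
        ("rare_duplets", 11, 200),
        ("rare_xyx", 201, 230),
        ("individual_inhibitions", 230, 300),
        ("individual_preferences", 700, 729),
    )
    if n_patterns == 729:
        return BandSpec(bands=canonical)
    scale = n_patterns / 729.0
    scaled = []
    for name, lo, hi in canonical:
        lo2 = max(1, round(lo * scale))
        hi2 = min(n_patterns, max(lo2, round(hi * scale)))
        scaled.append((name, lo2, hi2))
    return BandSpec(bands=tuple(scaled))


def ordinal_ranks(scores: np.ndarray, space: PatternSpace) -> np.ndarray:
    """Rank patterns from rarest (1) to most prevalent (9^n).

    Requires the full space (repeats included).  ``result[i]`` is the
    ordinal of pattern i; ties are broken lexicographically (the
    lexicographically smaller pattern takes the smaller ordinal).
    """
    if space.exclude_repeats:
        raise ValueError("ordinal ranks are defined over the full 9^n space")
    scores = np.asarray(scores, dtype=float)
    if len(scores) != len(space):
        raise ValueError("score vector does not match the pattern space")
    order = np.lexsort((np.arange(len(scores)), scores))
    ranks = np.empty(len(scores), dtype=int)
    ranks[order] = np.arange(1, len(scores) + 1)
    return ranks


def _rank_to_pattern(ranks: np.ndarray) -> np.ndarray:
    """Inverse map: index k-1 holds the pattern index with ordinal k."""
    inv = np.empty(len(ranks), dtype=int)
    inv[ranks - 1] = np.arange(len(ranks))
    return inv


def individuality_curve(
    scores_s1: pd.DataFrame,
    scores_s2: pd.DataFrame,
    space: PatternSpace,
    between_sessions: str = "first",
) -> IndividualityCurve:
    """Within- vs between-subject prevalence differences by ordinal rank.

    ``scores_s1`` / ``scores_s2``: DataFrames of raw scores over the full
    space, one row per subject (aligned indices), from sessions 1 and 2.
    ``between_sessions`` chooses the comparison population: other
    subjects' first sessions ('first') or both sessions ('both').
    """
    subjects = list(scores_s1.index)
    if list(scores_s2.index) != subjects:
        raise ValueError("session score tables must be aligned by subject")
    if len(subjects) < 2:
        raise ValueError("individuality curve needs at least 2 subjects")
    s1 = scores_s1.to_numpy(dtype=float)
    s2 = scores_s2.to_numpy(dtype=float)
    n_sub, n_pat = s1.shape
    if n_pat != len(space):
        raise ValueError("score tables do not match the pattern space")

    within = np.empty((n_sub, n_pat))
    between = np.empty((n_sub, n_pat))
    for i in range(n_sub):
        ranks = ordinal_ranks(s1[i], space)
        pat_at = _rank_to_pattern(ranks)  # ordinal k -> pattern index
        own1 = s1[i, pat_at]
        own2 = s2[i, pat_at]
        within[i] = np.abs(own1 - own2)
        others = np.delete(s1, i, axis=0)
        if between_sessions == "both":
            others = np.vstack([others, np.delete(s2, i, axis=0)])
        elif between_sessions != "first":
            raise ValueError(f"unknown between_sessions mode {between_sessions!r}")
        between[i] = np.abs(own1[None, :] - others[:, pat_at]).mean(axis=0)

    def sem(x: np.ndarray) -> np.ndarray:
        return x.std(axis=0, ddof=1) / np.sqrt(n_sub) if n_sub > 1 else np.zeros(n_pat)

    delta = between - within
    table = pd.DataFrame(
        {
            "within": within.mean(axis=0),
            "between": between.mean(axis=0),
            "within_se": sem(within),
            "between_se": sem(between),
            "delta": delta.mean(axis=0),
            "delta_se": sem(delta),
        },
        index=pd.Index(np.arange(1, n_pat + 1), name="ordinal"),
    )
    return IndividualityCurve(n=space.n, table=table, n_subjects=n_sub)


def band_top_patterns(
    rank_table: pd.DataFrame,
    space: PatternSpace,
    bands: BandSpec | None = None,
    top_k: int = 5,
) -> dict[str, list[tuple[str, int]]]:
    """Most frequent band members across subjects.

    ``rank_table``: one row per subject, one column per pattern, holding
    each pattern's ordinal for that subject.  For every band, counts how
    often each pattern's ordinal falls inside the band and returns the
    ``top_k`` (pattern label, count) pairs, ties broken lexicographically.
    """
    if bands is None:
        bands = default_bands(len(space))
    ranks = rank_table.to_numpy(dtype=int)
    labels = space.labels
    out: dict[str, list[tuple[str, int]]] = {}
    for name, lo, hi in bands.bands:
        counts = ((ranks >= lo) & (ranks <= hi)).sum(axis=0)
        order = np.lexsort((np.arange(len(counts)), -counts))
        chosen = [k for k in order if counts[k] > 0][:top_k]
        out[name] = [(labels[k], int(counts[k])) for k in chosen]
    return out


def data_driven_bands(
    curve: IndividualityCurve, window: int = 11
) -> list[int]:
    """Locate band boundaries at local minima of the smoothed delta curve."""
    delta = curve.delta
    kernel = np.ones(window) / window
    smooth = np.convolve(delta, kernel, mode="same")
    minima = [
        k + 1
        for k in range(1, len(smooth) - 1)
        if smooth[k] < smooth[k - 1] and smooth[k] <= smooth[k + 1]
    ]
    return minima


def familiar_subpatterns(digits: str, n: int = 3) -> list[tuple[int, ...]]:
    """Contiguous length-n subpatterns of a familiar number, deduplicated.

    '0' cannot occur in the task's 1-9 range and is dropped before
    extraction (an interpretation: the remaining order structure is
    preserved).
    """
    cleaned = [int(c) for c in digits if c != "0"]
    seen: list[tuple[int, ...]] = []
    for i in range(len(cleaned) - n + 1):
        pat = tuple(cleaned[i : i + n])
        if pat not in seen:
            seen.append(pat)
    return seen


@dataclass
class FamiliarTestResult:
    kind: str
    t: float
    p: float
    ks_d: float
    ks_p: float
    n_subjects: int
    per_subject: pd.Series = field(repr=False, default=None)


def familiar_pattern_test(
    scores_s1: pd.DataFrame,
    familiar: list[tuple[str, str, str]],
    space: PatternSpace,
    n: int = 3,
) -> dict[str, FamiliarTestResult]:
    """Test over-/under-representation of personally familiar patterns.

    For each subject and familiar kind, the statistic is the mean over
    her familiar length-n patterns of (own session-1 score - mean of the
    same pattern's score over all other subjects' session-1 sequences).
    Across subjects: one-sample two-sided t test against zero plus a KS
    normality check of the per-subject statistics.
    """
    if space.exclude_repeats:
        raise ValueError("familiar-pattern test uses the full pattern space")
    subjects = list(scores_s1.index)
    if len(subjects) < 3:
        raise ValueError("familiar-pattern test needs at least 3 subjects")
    values = scores_s1.to_numpy(dtype=float)
    col_sum = values.sum(axis=0)
    pat_index = {p: k for k, p in enumerate(space.patterns)}

    by_kind: dict[str, dict[str, list[tuple[int, ...]]]] = {}
    for sid, kind, digits in familiar:
        pats = familiar_subpatterns(digits, n=n)
        if sid in subjects and pats:
            by_kind.setdefault(kind, {}).setdefault(sid, []).extend(pats)

    results: dict[str, FamiliarTestResult] = {}
    n_sub = len(subjects)
    for kind, table in sorted(by_kind.items()):
        stats_per_subject = {}
        for sid, pats in table.items():
            i = subjects.index(sid)
            terms = []
            for pat in dict.fromkeys(pats):
                k = pat_index.get(pat)
                if k is None:
                    continue
                own = values[i, k]
                others_mean = (col_sum[k] - own) / (n_sub - 1)
                terms.append(own - others_mean)
            if terms:
                stats_per_subject[sid] = float(np.mean(terms))
        if len(stats_per_subject) < 3:
            raise ValueError(
                f"familiar kind {kind!r}: fewer than 3 subjects with usable patterns"
            )
        per = pd.Series(stats_per_subject).sort_index()
        x = per.to_numpy()
        tt = stats.ttest_1samp(x, 0.0)
        mu, sd = x.mean(), x.std(ddof=1)
        if sd > 0:
            ks = stats.kstest(x, "norm", args=(mu, sd))
            ks_d, ks_p = float(ks.statistic), float(ks.pvalue)
        else:
            ks_d, ks_p = float("nan"), float("nan")
        results[kind] = FamiliarTestResult(
            kind=kind,
            t=float(tt.statistic),
            p=float(tt.pvalue),
            ks_d=ks_d,
            ks_p=ks_p,
            n_subjects=len(per),
            per_subject=per,
        )
    return results
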