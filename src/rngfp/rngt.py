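"""Classical random-number-generation-task (RNGT) indices.

Two indices summarise how far a produced sequence departs from
mathematical randomness:

* **Redundancy** R = 1 - H/H_max, where H is the Shannon entropy of the
  digit frequencies and H_max = log2(9).  R = 0 for perfectly equal
  digit usage, R = 1 when a single digit is used.
* **Runs** (run-ups): the sequence is split into maximal strictly
  ascending runs and the index is the population variance of the run
  lengths, capturing the tendency to "count".  (Variants of this index
  exist in the literature; the ascending-runs variance is used here and
  alternatives are selectable.)

Sanity-check machinery mirrors the typical cohort table: per-session
means +/- SD, a Kolmogorov-Smirnov test of each index against a
log-normal distribution (moment-estimated parameters), and a paired t
test between sessions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .corpus import Corpus, DigitSequence

__all__ = [
    "redundancy",
    "runs_index",
    "ascending_run_lengths",
    "ks_lognormal",
    "paired_session_test",
    "rngt_table",
    "rngt_summary",
]


def redundancy(z: DigitSequence | list[int]) -> float:
    """Relative redundancy of digit usage: 1 - H/log2(9), in [0, 1]."""
    digits = z.as_array() if isinstance(z, DigitSequence) else np.asarray(z)
    counts = np.bincount(digits, minlength=10)[1:10].astype(float)
    total = counts.sum()
    if total < 1:
        raise ValueError("sequence must contain at least one digit")
    p = counts[counts > 0] / total
    h = float(-(p * np.log2(p)).sum())
    r = 1.0 - h / np.log2(9.0)
    return float(min(1.0, max(0.0, r)))


def ascending_run_lengths(z: DigitSequence | list[int]) -> list[int]:
    """Lengths of maximal blocks in which each digit exceeds its predecessor."""
    digits = list(z.as_array()) if isinstance(z, DigitSequence) else list(z)
    runs = []
    cur = 1
    for prev, nxt in zip(digits, digits[1:]):
        if nxt > prev:
            cur += 1
        else:
            runs.append(cur)
            cur = 1
    runs.append(cur)
    return runs


def runs_index(z: DigitSequence | list[int], variant: str = "ascending") -> float:
    """Seriation index: population variance of run lengths.

    variant 'ascending' segments maximal strictly ascending runs (any
    increase extends a run); 'ascending+descending' averages the
    ascending-run variance and its descending counterpart.
    """
    digits = list(z.as_array()) if isinstance(z, DigitSequence) else list(z)
    if len(digits) < 2:
        raise ValueError("runs index needs at least 2 digits")
    if variant == "ascending":
        lengths = ascending_run_lengths(digits)
    elif variant == "ascending+descending":
        up = ascending_run_lengths(digits)
        down = ascending_run_lengths([-d for d in digits])
        return float((np.var(up) + np.var(down)) / 2.0)
    else:
        raise ValueError(f"unknown runs variant {variant!r}")
    return float(np.var(lengths))


def ks_lognormal(values) -> tuple[float, float]:
    """One-sample KS test of positive values against a fitted log-normal.

    Log-values are compared with a normal distribution whose mean and SD
    are moment estimates from the same data (no small-sample correction,
    so the test is conservative).
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 5:
        raise ValueError("KS test needs at least 5 values")
    if np.any(v <= 0):
        raise ValueError("log-normal KS requires strictly positive values")
    logs = np.log(v)
    mu, sd = logs.mean(), logs.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate sample: zero variance on the log scale")
    res = stats.kstest(logs, "norm", args=(mu, sd))
    return float(res.statistic), float(res.pvalue)


@dataclass
class PairedTestResult:
    t: float
    p: float
    flag: str | None = None


def paired_session_test(v1, v2) -> PairedTestResult:
    """Paired t test between two aligned per-subject vectors."""
    a = np.asarray(v1, dtype=float)
    b = np.asarray(v2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must be aligned and equal length")
    if len(a) < 3:
        raise ValueError("paired test needs at least 3 subjects")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff, 0.0):
            return PairedTestResult(t=0.0, p=1.0, flag="identical")
        return PairedTestResult(
            t=np.inf if diff.mean() > 0 else -np.inf, p=0.0, flag="zero-variance"
        )
    res = stats.ttest_rel(a, b)
    return PairedTestResult(t=float(res.statistic), p=float(res.pvalue))


def rngt_table(corpus: Corpus, runs_variant: str = "ascending") -> pd.DataFrame:
    """Per-sequence RNGT record: subject, session, redundancy, runs."""
    rows = [
        {
            "subject_id": s.subject_id,
            "session": s.session,
            "redundancy": redundancy(s),
            "runs": runs_index(s, variant=runs_variant),
        }
        for s in corpus
    ]
    return pd.DataFrame(rows)


def rngt_summary(table: pd.DataFrame, sessions: tuple[int, int] = (1, 2)) -> dict:
    """Cohort summary: per-session mean +/- SD, KS-vs-lognormal, paired t tests."""
    out: dict = {"sessions": sessions, "indices": {}}
    s1, s2 = sessions
    t1 = table[table["session"] == s1].set_index("subject_id")
    t2 = table[table["session"] == s2].set_index("subject_id")
    common = t1.index.intersection(t2.index)
    for index_name in ("redundancy", "runs"):
        block = {}
        for label, t in (("session_1", t1), ("session_2", t2)):
            vals = t[index_name].to_numpy()
            entry = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1))}
            positive = vals[vals > 0]
            if len(positive) >= 5:
                d, p = ks_lognormal(positive)
                entry["ks_d"], entry["ks_p"] = d, p
            block[label] = entry
        paired = paired_session_test(
            t1.loc[common, index_name], t2.loc[common, index_name]
        )
        block["paired_t"] = {"t": paired.t, "p": paired.p, "flag": paired.flag}
        out["indices"][index_name] = block
    return out
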