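"""Corpus representation, TSV I/O, and subject-level exclusion filters.

A corpus is a collection of digit sequences (digits 1-9), one per
subject x session, optionally with per-digit onset times in seconds.
Subjects can be screened out for grossly non-uniform digit usage
(cohort-level z-score of a chi-square uniformity statistic) or for
excessively long pauses between responses.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

__all__ = [
    "DigitSequence",
    "Corpus",
    "CorpusError",
    "read_corpus",
    "write_corpus",
    "read_familiar",
    "filter_subjects",
]

DIGITS = tuple(range(1, 10))


class CorpusError(ValueError):
    """Raised for malformed corpus files or invalid sequences."""


@dataclass(frozen=True)
class DigitSequence:
    """One subject-session sequence of digits drawn from 1-9.

    Parameters
    ----------
    subject_id : str
        Opaque subject identifier.
    session : int
        Session number (1-based).
    digits : tuple of int
        The produced digits, each in 1..9, in production order.
    onsets : tuple of float, optional
        Onset time in seconds of each digit; strictly increasing and the
        same length as ``digits`` when present.
    """

    subject_id: str
    session: int
    digits: tuple[int, ...]
    onsets: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.session < 1:
            raise CorpusError(f"session must be >= 1, got {self.session}")
        if len(self.digits) < 1:
            raise CorpusError("sequence must contain at least one digit")
        bad = [d for d in self.digits if d not in range(1, 10)]
        if bad:
            raise CorpusError(f"digits outside 1..9: {sorted(set(bad))}")
        if self.onsets is not None:
            if len(self.onsets) != len(self.digits):
                raise CorpusError("onsets length must match digits length")
            diffs = np.diff(self.onsets)
            if len(diffs) and not np.all(diffs > 0):
                raise CorpusError("onsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.digits)

    @property
    def key(self) -> tuple[str, int]:
        return (self.subject_id, self.session)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.digits, dtype=np.int8)

    def as_string(self) -> str:
        return "".join(str(d) for d in self.digits)


@dataclass
class Corpus:
    """A set of digit sequences with unique (subject_id, session) keys."""

    sequences: list[DigitSequence] = field(default_factory=list)
    exclusion_log: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [s.key for s in self.sequences]
        if len(keys) != len(set(keys)):
            seen: set[tuple[str, int]] = set()
            for k in keys:
                if k in seen:
                    raise CorpusError(f"duplicate (subject_id, session) key: {k}")
                seen.add(k)

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)

    @property
    def subjects(self) -> list[str]:
        out: list[str] = []
        for s in self.sequences:
            if s.subject_id not in out:
                out.append(s.subject_id)
        return out

    @property
    def sessions(self) -> list[int]:
        return sorted({s.session for s in self.sequences})

    def get(self, subject_id: str, session: int) -> DigitSequence:
        for s in self.sequences:
            if s.key == (subject_id, session):
                return s
        raise KeyError((subject_id, session))

    def subset(self, subject_ids: Iterable[str]) -> "Corpus":
        keep = set(subject_ids)
        return Corpus(
            sequences=[s for s in self.sequences if s.subject_id in keep],
            exclusion_log=list(self.exclusion_log),
        )

    def session_view(self, session: int) -> list[DigitSequence]:
        return [s for s in self.sequences if s.session == session]


def _parse_row(lineno: int, row: list[str], has_onsets: bool) -> DigitSequence:
    if len(row) < 3:
        raise CorpusError(f"line {lineno}: expected at least 3 columns, got {len(row)}")
    subject_id, session_s, seq_s = row[0], row[1], row[2]
    try:
        session = int(session_s)
    except ValueError as exc:
        raise CorpusError(f"line {lineno}: session {session_s!r} is not an integer") from exc
    bad_chars = sorted({c for c in seq_s if c not in "123456789"})
    if bad_chars:
        raise CorpusError(
            f"line {lineno}: invalid characters {bad_chars} in sequence (allowed: 1-9)"
        )
    digits = tuple(int(c) for c in seq_s)
    onsets: tuple[float, ...] | None = None
    if has_onsets and len(row) > 3 and row[3].strip():
        try:
            onsets = tuple(float(x) for x in row[3].split(","))
        except ValueError as exc:
            raise CorpusError(f"line {lineno}: malformed onsets column") from exc
    return DigitSequence(subject_id=subject_id, session=session, digits=digits, onsets=onsets)


def read_corpus(path: str | Path | io.TextIOBase) -> Corpus:
    """Read a corpus TSV.

    Expected columns: ``subject_id``, ``session``, ``sequence`` and an
    optional ``onsets`` column holding comma-separated seconds.  The
    sequence column is a contiguous run of characters '1'-'9'.
    """
    if isinstance(path, (str, Path)):
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(p)
        text = p.read_text(encoding="utf-8")
    else:
        text = path.read()
    lines = text.splitlines()
    if not lines:
        raise CorpusError("empty corpus file")
    header = lines[0].rstrip("\n").split("\t")
    required = ["subject_id", "session", "sequence"]
    if header[: len(required)] != required:
        raise CorpusError(
            f"malformed header: expected columns {required} (optionally 'onsets'), got {header}"
        )
    has_onsets = len(header) > 3 and header[3] == "onsets"
    sequences: list[DigitSequence] = []
    errors: list[str] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        try:
            sequences.append(_parse_row(lineno, line.split("\t"), has_onsets))
        except CorpusError as exc:
            errors.append(str(exc))
    if errors:
        raise CorpusError("rejected rows:\n" + "\n".join(errors))
    return Corpus(sequences=sequences)


def write_corpus(corpus: Corpus, path: str | Path | io.TextIOBase) -> None:
    """Write a corpus as TSV (round-trips with :func:`read_corpus`)."""
    any_onsets = any(s.onsets is not None for s in corpus)
    cols = ["subject_id", "session", "sequence"] + (["onsets"] if any_onsets else [])
    out = ["\t".join(cols)]
    for s in corpus:
        row = [s.subject_id, str(s.session), s.as_string()]
        if any_onsets:
            row.append("" if s.onsets is None else ",".join(repr(t) for t in s.onsets))
        out.append("\t".join(row))
    text = "\n".join(out) + "\n"
    if isinstance(path, (str, Path)):
        Path(path).write_text(text, encoding="utf-8")
    else:
        path.write(text)


def read_familiar(path: str | Path) -> list[tuple[str, str, str]]:
    """Read a familiar-number TSV: subject_id, kind, digits.

    ``kind`` is one of birthdate / phone / postal; ``digits`` may contain
    '0' characters (handled downstream).
    """
    p = Path(path)
    lines = p.read_text(encoding="utf-8").splitlines()
    header = lines[0].split("\t")
    if header[:3] != ["subject_id", "kind", "digits"]:
        raise CorpusError(f"malformed familiar-number header: {header}")
    rows = []
    for line in lines[1:]:
        if not line.strip():
            continue
        sid, kind, digits = line.split("\t")[:3]
        if not digits.isdigit():
            raise CorpusError(f"non-digit familiar entry for {sid}: {digits!r}")
        rows.append((sid, kind, digits))
    return rows


def uniformity_statistic(digits_pooled: np.ndarray) -> float:
    """Chi-square statistic of a pooled digit histogram against uniform over 1..9."""
    counts = np.bincount(digits_pooled, minlength=10)[1:10].astype(float)
    expected = counts.sum() / 9.0
    return float(((counts - expected) ** 2 / expected).sum())


def filter_subjects(
    corpus: Corpus,
    sigma_threshold: float = 3.5,
    max_pause: float = 15.0,
    per_sequence: bool = False,
) -> Corpus:
    """Apply the cohort's subject-exclusion screens.

    Two screens, applied at the subject level:

    1. *Uniformity*: a chi-square statistic of each subject's pooled digit
       histogram against the uniform distribution over nine digits is
       z-scored across the cohort; subjects more than ``sigma_threshold``
       standard deviations above the cohort mean are excluded.
    2. *Pauses*: subjects with any inter-onset gap above ``max_pause``
       seconds are excluded (only testable where onsets are recorded;
       sequences without onsets pass).

    With ``per_sequence=True`` the uniformity statistic is computed per
    sequence instead of pooled per subject (a subject is excluded if any
    of their sequences is an outlier).

    Idempotent: the surviving cohort, re-filtered, is unchanged provided
    the surviving statistics are not re-centred into new outliers; the
    exclusion log accumulates.
    """
    if len(corpus) == 0:
        raise CorpusError("cannot filter an empty corpus")
    if sigma_threshold <= 0:
        raise ValueError("sigma_threshold must be positive")

    subjects = corpus.subjects
    excluded: dict[str, str] = {}

    # pause screen
    for s in corpus:
        if s.onsets is not None and len(s.onsets) > 1:
            if float(np.max(np.diff(s.onsets))) > max_pause:
                excluded.setdefault(s.subject_id, "pause")

    # uniformity screen (on subjects surviving the pause screen)
    candidates = [sid for sid in subjects if sid not in excluded]
    if per_sequence:
        stats = []
        owners = []
        for s in corpus:
            if s.subject_id in candidates:
                stats.append(uniformity_statistic(s.as_array()))
                owners.append(s.subject_id)
    else:
        stats = []
        owners = []
        for sid in candidates:
            pooled = np.concatenate(
                [s.as_array() for s in corpus if s.subject_id == sid]
            )
            stats.append(uniformity_statistic(pooled))
            owners.append(sid)
    stats_arr = np.asarray(stats, dtype=float)
    if len(stats_arr) >= 2 and stats_arr.std() > 0:
        z = (stats_arr - stats_arr.mean()) / stats_arr.std()
        for owner, zval in zip(owners, z):
            if zval > sigma_threshold:
                excluded.setdefault(owner, "uniformity")

    log = list(corpus.exclusion_log) + sorted(excluded.items())
    return Corpus(
        sequences=[s for s in corpus if s.subject_id not in excluded],
        exclusion_log=log,
    )
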