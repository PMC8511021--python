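"""Synthetic human-RNG cohort generator.

The generator realises, as simply as possible, the three mechanisms the
analysis assumes about human pseudorandom digit production:

1. **Pattern reuse with variation** — each subject owns a small set of
   preferred patterns (length 3-4).  With probability ``template_rate``
   the next digits come from a preferred pattern instance, which with
   probability ``edit_noise`` first receives one random edit (insertion,
   deletion, substitution, or adjacent transposition), obscuring the
   recurring theme.
2. **Repetition suppression and seriation** — outside templates, digits
   come from a near-uniform baseline that down-weights repeating the
   previous digit by (1 - repetition_suppression) and up-weights the
   successor digit by the seriation bias (the "counting" tendency).
3. **Person-specific preferences and inhibitions** — preferred/inhibited
   sets have a shared (cohort-wide) part and a subject-specific part
   whose influence scales with the individuality strength kappa; at
   kappa = 0 every subject runs the identical shared profile and the
   cohort is exchangeable.

Sequences are fully determined by (master_seed, subject index, session):
every (subject, session) pair has its own counter-derived random stream,
so adding subjects or sessions never perturbs existing sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus import Corpus, DigitSequence

__all__ = [
    "SubjectProfile",
    "CohortSpec",
    "sample_profile",
    "generate_sequence",
    "generate_corpus",
    "generate_familiar",
]


@dataclass(frozen=True)
class SubjectProfile:
    """Generator parameters for one synthetic subject."""

    subject_id: str
    index: int
    preferred: tuple[tuple[tuple[int, ...], float], ...]  # (pattern, weight > 0)
    inhibited: tuple[tuple[tuple[int, ...], float], ...]  # (pattern, suppression in [0,1])
    repetition_suppression: float
    seriation_bias: float
    edit_noise: float
    template_rate: float
    familiar: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        pref = {p for p, _ in self.preferred}
        inhib = {p for p, _ in self.inhibited}
        if pref & inhib:
            raise ValueError("preferred and inhibited pattern sets must be disjoint")
        for name in ("repetition_suppression", "seriation_bias", "edit_noise", "template_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for _, w in self.preferred:
            if w <= 0:
                raise ValueError("preferred-pattern weights must be positive")
        for _, s in self.inhibited:
            if not 0.0 <= s <= 1.0:
                raise ValueError("suppression strengths must lie in [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    """Study-level conditions for a synthetic cohort.

    Defaults emulate the reference study conditions: 115 subjects, two
    300-digit sessions 40 minutes apart, plus a third session one week
    later for the first 20 subjects.
    """

    n_subjects: int = 115
    sessions: int = 2
    third_session_subjects: int = 20
    sequence_length: int = 300
    individuality_strength: float = 1.0  # kappa; 0 => shared profile
    session_drift: float = 0.1
    template_rate: float = 0.35
    edit_noise: float = 0.3
    repetition_suppression: float = 0.8
    seriation_bias: float = 0.08
    n_shared_preferred: int = 2
    n_subject_preferred: int = 10
    n_shared_inhibited: int = 4
    n_subject_inhibited: int = 6
    inhibition_strength: float = 0.9
    familiar_boost: float = 0.0  # weight of familiar-number subpatterns as templates
    familiar_style: str = "birthdate"  # 'birthdate' (shared 19XX structure) or 'random'
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.sessions < 1 or self.sequence_length < 1:
            raise ValueError("cohort sizes must be positive")
        if self.individuality_strength < 0:
            raise ValueError("individuality_strength must be >= 0")
        if not 0.0 <= self.session_drift <= 1.0:
            raise ValueError("session_drift must lie in [0, 1]")


def _subject_id(i: int) -> str:
    return f"S{i + 1:03d}"


def _draw_repeat_free_pattern(rng: np.random.Generator, length: int) -> tuple[int, ...]:
    out = [int(rng.integers(1, 10))]
    while len(out) < length:
        d = int(rng.integers(1, 10))
        if d != out[-1]:
            out.append(d)
    return tuple(out)


def _draw_patterns(
    rng: np.random.Generator, count: int, taken: set[tuple[int, ...]]
) -> list[tuple[int, ...]]:
    """Distinct repeat-free patterns of length 3-4 avoiding ``taken``."""
    out: list[tuple[int, ...]] = []
    while len(out) < count:
        length = int(rng.integers(3, 5))
        p = _draw_repeat_free_pattern(rng, length)
        if p not in taken:
            taken.add(p)
            out.append(p)
    return out


def _familiar_digits(rng: np.random.Generator, style: str = "birthdate") -> str:
    """A familiar digit string.

    'birthdate': DDMMYYYY — realistically shares the 19XX year structure
    across subjects (may contain '0').  'random': 8 iid digits 0-9, so
    subjects' familiar patterns rarely coincide.
    """
    if style == "random":
        return "".join(str(int(d)) for d in rng.integers(0, 10, 8))
    if style != "birthdate":
        raise ValueError(f"unknown familiar_style {style!r}")
    day = int(rng.integers(1, 29))
    month = int(rng.integers(1, 13))
    year = int(rng.integers(1950, 2006))
    return f"{day:02d}{month:02d}{year:04d}"


def sample_profile(spec: CohortSpec, index: int) -> SubjectProfile:
    """Deterministic subject profile from (master_seed, subject index).

    The shared profile component is drawn from the master seed alone and
    is identical for every subject; the subject-specific component is
    drawn from the subject's own stream and its weights/suppressions are
    scaled by the individuality strength kappa.  kappa = 0 drops the
    subject-specific part entirely, leaving one shared profile.
    """
    kappa = spec.individuality_strength
    rng_shared = np.random.default_rng([spec.master_seed, 977])
    taken: set[tuple[int, ...]] = set()
    shared_pref = _draw_patterns(rng_shared, spec.n_shared_preferred, taken)
    shared_pref_w = rng_shared.uniform(0.5, 1.5, size=len(shared_pref))
    shared_inh = _draw_patterns(rng_shared, spec.n_shared_inhibited, taken)

    preferred = list(zip(shared_pref, shared_pref_w.tolist()))
    inhibited = [(p, spec.inhibition_strength) for p in shared_inh]

    rng_subj = np.random.default_rng([spec.master_seed, 1000 + index])
    subj_pref = _draw_patterns(rng_subj, spec.n_subject_preferred, taken)
    subj_pref_w = rng_subj.uniform(0.5, 1.5, size=len(subj_pref))
    subj_inh = _draw_patterns(rng_subj, spec.n_subject_inhibited, taken)
    if kappa > 0:
        preferred += list(zip(subj_pref, (kappa * subj_pref_w).tolist()))
        supp = min(1.0, spec.inhibition_strength * min(1.0, kappa))
        inhibited += [(p, supp) for p in subj_inh]

    familiar: tuple[str, ...] = ()
    if spec.familiar_boost > 0:
        rng_fam = np.random.default_rng([spec.master_seed, 4099, index])
        familiar = (_familiar_digits(rng_fam, spec.familiar_style),)
        fam_pats = []
        for digits in familiar:
            cleaned = [int(c) for c in digits if c != "0"]
            for j in range(len(cleaned) - 2):
                pat = tuple(cleaned[j : j + 3])
                if pat not in {p for p, _ in preferred} and pat not in fam_pats:
                    fam_pats.append(pat)
        inh_set = {p for p, _ in inhibited}
        preferred += [
            (p, spec.familiar_boost) for p in fam_pats if p not in inh_set
        ]

    return SubjectProfile(
        subject_id=_subject_id(index),
        index=index,
        preferred=tuple(preferred),
        inhibited=tuple(inhibited),
        repetition_suppression=spec.repetition_suppression,
        seriation_bias=spec.seriation_bias,
        edit_noise=spec.edit_noise,
        template_rate=spec.template_rate,
        familiar=familiar,
    )


def _edit_pattern(pattern: tuple[int, ...], rng: np.random.Generator) -> list[int]:
    """One random edit: insertion, deletion, substitution, or adjacent swap."""
    p = list(pattern)
    ops = ["insert", "substitute"]
    if len(p) > 1:
        ops += ["delete", "transpose"]
    op = ops[int(rng.integers(0, len(ops)))]
    if op == "insert":
        pos = int(rng.integers(0, len(p) + 1))
        p.insert(pos, int(rng.integers(1, 10)))
    elif op == "delete":
        p.pop(int(rng.integers(0, len(p))))
    elif op == "substitute":
        pos = int(rng.integers(0, len(p)))
        choices = [d for d in range(1, 10) if d != p[pos]]
        p[pos] = choices[int(rng.integers(0, len(choices)))]
    else:  # transpose adjacent
        pos = int(rng.integers(0, len(p) - 1))
        p[pos], p[pos + 1] = p[pos + 1], p[pos]
    return p


def _session_weights(
    profile: SubjectProfile, spec: CohortSpec, session: int
) -> np.ndarray:
    """Preferred-pattern weights with multiplicative session drift."""
    w = np.array([wt for _, wt in profile.preferred], dtype=float)
    if spec.session_drift > 0 and len(w):
        rng = np.random.default_rng(
            [spec.master_seed, profile.index, session, 131]
        )
        w = w * np.exp(spec.session_drift * rng.normal(size=len(w)))
    return w


def generate_sequence(
    profile: SubjectProfile, spec: CohortSpec, session: int
) -> DigitSequence:
    """One synthetic session sequence, deterministic in (seed, subject, session)."""
    rng = np.random.default_rng([spec.master_seed, profile.index, session, 7919])
    L = spec.sequence_length
    weights = _session_weights(profile, spec, session)
    patterns = [p for p, _ in profile.preferred]
    wsum = weights.sum()
    probs = weights / wsum if wsum > 0 else None
    inhibited = list(profile.inhibited)
    rho = profile.repetition_suppression
    out: list[int] = []
    buffer: list[int] = []
    while len(out) < L:
        if buffer:
            out.append(buffer.pop(0))
            continue
        if probs is not None and rng.random() < profile.template_rate:
            k = int(rng.choice(len(patterns), p=probs))
            instance = list(patterns[k])
            if rng.random() < profile.edit_noise:
                instance = _edit_pattern(patterns[k], rng)
            buffer = instance
            out.append(buffer.pop(0))
            continue
        # baseline emission
        w = np.ones(9, dtype=float)
        if out:
            prev = out[-1]
            w[prev - 1] *= 1.0 - rho
            if prev < 9:
                w[prev] *= 1.0 + profile.seriation_bias
        for _ in range(10):  # resampling cap for inhibitions
            d = int(rng.choice(9, p=w / w.sum())) + 1
            completes = any(
                len(out) >= len(p) - 1 and tuple(out[len(out) - len(p) + 1 :]) + (d,) == p
                for p, _ in inhibited
            )
            if not completes:
                break
            supp = max(s for p, s in inhibited if tuple(out[len(out) - len(p) + 1 :]) + (d,) == p)
            if rng.random() >= supp:
                break
        out.append(d)
    return DigitSequence(
        subject_id=profile.subject_id, session=session, digits=tuple(out[:L])
    )


def generate_corpus(spec: CohortSpec) -> Corpus:
    """Full synthetic cohort: per-subject profiles, per-session sequences."""
    sequences = []
    for i in range(spec.n_subjects):
        profile = sample_profile(spec, i)
        n_sessions = spec.sessions + (1 if i < spec.third_session_subjects else 0)
        for session in range(1, n_sessions + 1):
            sequences.append(generate_sequence(profile, spec, session))
    return Corpus(sequences=sequences)


def generate_familiar(
    spec: CohortSpec, kind: str = "birthdate"
) -> list[tuple[str, str, str]]:
    """Familiar-number table aligned with the cohort's profiles.

    The same digit strings the profiles see: with ``familiar_boost`` = 0
    they are independent of the produced sequences (null condition); with
    a positive boost the generator over-emits their subpatterns (planted
    condition for power analyses).
    """
    rows = []
    for i in range(spec.n_subjects):
        rng_fam = np.random.default_rng([spec.master_seed, 4099, i])
        rows.append((_subject_id(i), kind, _familiar_digits(rng_fam, spec.familiar_style)))
    return rows
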