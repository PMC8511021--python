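# rngfp

Cognitive-fingerprint analysis of human random digit sequences.

When people are asked to produce a "random" series of digits (1–9), they
fail in person-specific ways: each individual reuses a small repertoire of
preferred patterns — usually obscured by small variations — and avoids
patterns they privately judge non-random. `rngfp` implements a complete
pipeline for quantifying this individuality and for deciding whether two
digit sequences were produced by the same person. It is aimed at
researchers in cognitive psychology and behavioural neuroscience who work
with random-number-generation (RNG) task data.

## The method

**Variation-tolerant pattern prevalence.** For a pattern *m* (an n-gram
over digits 1–9, n = 1…6) and a sequence *z* of length *L*, the
Damerau–Levenshtein score is

    s(m, z) = (1/L) · Σ_w 1 / (d(m, w) + 1)

where *w* runs over all length-|m| windows of *z* and *d* is the
optimal-string-alignment Damerau–Levenshtein edit distance (unit-cost
insertions, deletions, substitutions, adjacent transpositions). Exact
occurrences contribute 1; near misses contribute fractions. An
exact-match count (windows equal to *m*, divided by *L*) serves as the
tolerance-free baseline.

**Sequence distance.** Scores are z-scored per pattern across the corpus,
and the distance between two sequences over the length-n space is

    d_n(z1, z2) = sqrt( Σ_i tanh²( s_i(z1) − s_i(z2) ) )

the tanh damping caps any single pattern's contribution, so a few
strategy shifts cannot dominate. Adjacent-repeat patterns ("11", "555")
are excluded from the identification space.

**Identification and inference.** A pair of sequences is classified
*match* (same author) when its distance falls below a threshold; sweeping
the threshold gives the ROC, summarised by the Mann–Whitney rank AUC.
Standard errors and z tests (AUC trend across pattern lengths,
DLS-vs-baseline differences) come from leave-one-subject-out jackknife
replicates that recompute the entire pipeline.

**Individuality structure.** Ranking all 9³ length-3 patterns from each
subject's rarest to most preferred and comparing within-subject vs
between-subject score differences localises the fingerprint: elevated
gaps at the common end are individual preferences, at the rare end
individual inhibitions. Classical RNGT indices (redundancy, ascending-run
variance) and a test for over-representation of personally familiar
numbers (birthdates etc.) round out the toolkit.

**Synthetic cohorts.** Because RNG-task corpora are rarely shareable, the
package includes a generative model of the assumed mechanisms —
person-specific pattern reuse with random edits, repetition suppression,
seriation, inhibitions — with a single individuality-strength dial κ
(κ = 0 gives an exchangeable cohort). Every analysis is testable
end-to-end without any external data.

## Worked example

```python
from rngfp import CohortSpec, generate_corpus, identification_analysis, trend_test

corpus = generate_corpus(
    CohortSpec(n_subjects=15, sessions=2, third_session_subjects=0, master_seed=1)
)
res = identification_analysis(corpus, lengths=[1, 2, 3], jackknife=True)
print(res.summary.round(4))
tt = trend_test(res.replicates)
print(f"trend z = {tt.z:.2f}, p = {tt.p:.3g}")
```

prints

```
      auc      se  n_match  n_non_match
n
1  0.8832  0.0664       15          210
2  0.9644  0.0241       15          210
3  0.9689  0.0197       15          210
trend z = 1.78, p = 0.0746
```

Reading: with only 300 digits per session, a same-author pair of this
synthetic cohort is closer than a different-author pair 88–97% of the
time (AUC), already well above chance (0.5) for single-digit preferences
and improving with pattern length; the jackknife `se` column quantifies
subject-level uncertainty, and the trend z tests whether the increase
with length is systematic. More narrated walkthroughs live in
`examples/` (one script per capability), and a thin CLI (`rngfp
simulate|score|identify|rngt|individuality|report`) wraps the same
functions for shell use.

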