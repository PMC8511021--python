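# Methods

## Scope and model

`rngfp` analyses corpora of human-produced pseudorandom digit sequences
(digits 1–9, typically 300 per session, two or three sessions per
subject). The working hypothesis it operationalises: each person's
random generation process reuses a small set of predominant patterns,
obscured by minor variations, and suppresses patterns that feel
non-random to them — so sequences carry a stable, person-specific
signature.

## Edit distance

`dl_distance` implements the **optimal-string-alignment (OSA)** variant
of the Damerau–Levenshtein distance: unit-cost insertions, deletions,
substitutions and adjacent transpositions, with the restriction that no
element is edited after participating in a transposition. OSA is the
standard single-table dynamic program; the distinction from the
unrestricted variant is immaterial for patterns of length ≤ 6 (the two
variants differ only on contrived cases such as d("31","123"), 3 under
OSA vs 2 unrestricted). OSA is not a true metric — the triangle
inequality can fail by 1 in corner cases — which is why the test suite
sweeps triples and bounds the violation rather than asserting the
inequality universally. Symmetry and identity-of-indiscernibles hold
universally.

## Prevalence score

`pattern_score` slides the pattern over every position where a
full-length window fits (positions 1 … L−n+1; trailing short windows are
not scored, since comparing a pattern against a truncated fragment would
conflate truncation with edits) and returns `(1/L) Σ 1/(d+1)`. The
normalisation is by the sequence length L, not the window count; the
difference is a constant factor absorbed by the per-pattern
standardization downstream. Consequences used by the tests:

* every score lies in [0, 1];
* for n = 1 the score is an exact affine image of the digit count,
  `s = 0.5 + 0.5·count/L`, so length-1 identification is *identical by
  design* between the edit-tolerant and exact-count routes.

`score_vector` computes all patterns of a space at once: the sequence's
windows are deduplicated (there are at most 9^n distinct windows), the
OSA dynamic program runs per (pattern, distinct window) pair in a
numba-compiled kernel, and counts weight the terms. A vectorised NumPy
fallback implements the identical contract; both are verified against
the naive per-pattern loop to 1e−12.

Pattern spaces are enumerated lexicographically. Identification uses the
repeat-free space (patterns with adjacent equal digits removed,
9·8^(n−1) patterns) because people use adjacent-repeat patterns too
inconsistently to help; the individuality analysis deliberately uses the
full 9^n space, where same-digit triplets appear as universal
exceptions. This asymmetry is intentional.

## Standardization and distance

Scores are z-scored per pattern (column) over all sequences entering the
analysis — both paired sessions pooled, so the pair classifier is
treated symmetrically; population (ddof = 0) SD; zero-variance columns
map to zero. The robust distance is the Euclidean norm of
tanh-transformed coordinate differences: each pattern's contribution is
strictly increasing in the standardized gap but saturates below 1, so
the distance is bounded by sqrt(#patterns) and outliers in either
direction are down-weighted. The plain Euclidean norm is available for
comparison (`robust=False`).

Pairing: match/non-match pairs are cross-session by default (every
session-1 sequence against every session-2 sequence), so both labels
share the same session structure and practice/fatigue effects cancel; an
all-pairs scheme is selectable. Subjects missing a session are skipped
with a warning.

## Identification inference

AUC is computed in Mann–Whitney rank form (ties count ½), which equals
the trapezoidal area under the complete ROC; operating points at every
distinct distance are emitted for plotting. Inference uses
leave-one-**subject**-out jackknife — deleting a subject removes all
their sequences and all pairs touching them, restoring independence
between replicates — with SE = sqrt((n−1)/n · Σ(θ_i − θ̄)²). The trend
test regresses each replicate's AUC on pattern length (OLS) and refers
mean slope / jackknife SE to the standard normal; the difference test
does the same for aligned replicate differences (one- or two-tailed).
Degenerate cases (zero slope, zero replicate variance) are returned with
explicit flags instead of NaNs.

## RNGT indices

Redundancy R = 1 − H/log2(9) with H the Shannon entropy of digit
frequencies (fraction scale: 0 = perfectly equal usage, 1 = one digit).
The runs index is the population variance of maximal strictly-ascending
run lengths; published "runs" scores vary between tools
(ascending-only vs both directions, any-increase vs increment-of-one),
so the variant is a parameter, with ascending/any-increase as default.
The log-normality check is a one-sample KS test of log-values against a
normal with moment-estimated parameters; estimating parameters from the
same sample makes the test conservative (the Lilliefors effect), which is
mirrored deliberately rather than corrected, since the procedure itself
is the object of interest. Session comparisons use the classical paired
t test, with zero-variance difference vectors flagged.

## Individuality analysis

For each subject, ordinal ranks 1 … 9³ order patterns from her rarest to
most prevalent (session-1 scores; ties broken lexicographically). At
each ordinal the *within* difference is |s1 − s2| for that subject's
rank-k pattern, and the *between* difference is the mean |s1 − s1'|
against all other subjects (their session-1 scores by default; both
sessions selectable). Absolute differences are used, making
delta = between − within a non-negatively-biased individuality measure.
Elevated delta at high ordinals indicates person-specific preferences;
at low (but not lowest) ordinals, person-specific inhibitions; the very
lowest ordinals are universal exceptions (same-digit triplets avoided by
everyone) where delta stays near zero.

Bands on the ordinal axis default to the canonical printed ranges
(universal exceptions [1,10], rare duplets [11,200], rare x-y-x
[201,230], individual inhibitions [230,300], individual preferences
[700,729]) — reproduced verbatim including the overlap at 230 and the
unassigned middle; a data-driven mode locates local minima of the delta
curve smoothed with an 11-point moving average. For other space sizes
the ranges are scaled proportionally.

**Familiar numbers.** Because '0' cannot occur in the task alphabet,
zeros are dropped from familiar digit strings before extracting all
contiguous length-3 subpatterns (deduplicated per subject); this
preserves the residual order structure but is an interpretation, flagged
as such. Each subject's statistic is the mean own-minus-others score
difference over her familiar patterns; a one-sample two-sided t test
across subjects (plus a KS normality check) per familiar kind. Note a
structural subtlety: when many subjects share familiar subpatterns (the
19XX year block of birthdates), the per-subject statistics are
negatively coupled — own-vs-others differences at a common pattern sum
to ~0 — and the t test becomes conservative. Calibration checks
therefore use random familiar strings; with realistic birthdates the
test errs on the safe side.

## Synthetic cohort generator

The generator realises exactly the mechanisms the analysis assumes, as
simply as possible. Per emitted digit: with probability `template_rate`
a preferred pattern (selected by weight) is instantiated, receiving one
random edit with probability `edit_noise`; otherwise a baseline draw
down-weights repeating the previous digit by (1 −
`repetition_suppression`), up-weights the successor digit by
`seriation_bias`, and resamples (with the pattern's suppression
probability) any digit that would complete an inhibited pattern.
Preferred/inhibited sets have a shared cohort-wide part and a
subject-specific part whose weights scale with the individuality
strength κ; κ = 0 leaves one shared profile (exchangeable cohort).
Session-specific multiplicative jitter on template weights
(`session_drift`) models strategy drift between sessions. Every
(subject, session) stream is derived from the master seed by a counter
scheme, so enlarging a cohort never perturbs existing sequences.

Defaults (chosen once, to place the default cohort in the empirically
reported regime of strong identifiability with near-uniform digit
marginals): 115 subjects × 2 × 300 digits with a 20-subject third
session; `template_rate` 0.35, `edit_noise` 0.3,
`repetition_suppression` 0.8, `seriation_bias` 0.08, 2 shared + 10
subject-specific preferred patterns (lengths 3–4, weights U(0.5, 1.5)),
4 shared + 6 subject-specific inhibited patterns (suppression 0.9),
κ = 1, `session_drift` 0.1. Familiar numbers are birthdate-shaped
(DDMMYYYY) by default or fully random; `familiar_boost` > 0 plants
over-emission of their subpatterns for power analyses.

What the generator does *not* emulate: temporal nonstationarity within a
session, response-time structure, digit-span limits, or the messiness of
human exact-repetition behaviour. One visible consequence: exact bigram
counts are cleaner in synthetic cohorts than in humans, so the
exact-count baseline can peak higher at n = 2 than the edit-tolerant
route — the decisive structure (exact counts collapsing at n ≥ 4 while
edit-tolerant scores hold up) is reproduced, but passing tests on
synthetic cohorts show method correctness, not human effect sizes.

## Numerical and size choices

* Optimised and naive scoring agree to 1e−12 (additive); standardized
  column means are checked to 1e−9.
* Ordinal and band tie-breaks are lexicographic, making every analysis
  deterministic.
* Analyses in the tests and the acceptance script use 30-subject
  cohorts (12 for the familiar-test simulations) and pattern lengths
  1–5: the repeat-free length-6 space (294,912 patterns) costs an order
  of magnitude more scoring time without adding qualitative structure at
  this cohort size. These are the package's own problem-size choices.
* The uniformity screen z-scores a chi-square statistic of pooled digit
  counts across the cohort (> 3.5 σ above the cohort mean excludes the
  subject); the pause screen applies only where onset times exist.
  Re-filtering a filtered cohort is a no-op in practice, but re-z-scoring
  can in principle create new outliers; the screen is applied once.

## Known limitations

* OSA rather than unrestricted Damerau–Levenshtein (a deliberate,
  documented choice; the difference cannot matter for n ≤ 6 windows).
* The familiar-number test's conservativeness under shared familiar
  structure (see above) means real-birthdate nulls sit below the nominal
  α — its negative results are trustworthy, its power near the boundary
  is understated.
* Jackknife z statistics use the normal reference distribution without a
  t correction, consistent with the replicate counts (≥ 30 subjects)
  the method targets.
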