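"""Same-author identification from two 300-digit sessions.

Scores every sequence against all length-n patterns with the
edit-tolerant prevalence score, standardizes per pattern, computes
tanh-damped distances for all cross-session pairs, and sweeps a match
threshold (summarised by the AUC).  Jackknife (leave-one-subject-out)
gives standard errors and a trend test across pattern lengths.
"""

from rngfp import CohortSpec, generate_corpus, identification_analysis, trend_test

corpus = generate_corpus(
    CohortSpec(n_subjects=15, sessions=2, third_session_subjects=0, master_seed=1)
)
res = identification_analysis(corpus, lengths=[1, 2, 3], jackknife=True)
print(res.summary.round(4))
print("-> auc is the probability that a same-author pair of sequences lies"
      " closer than a different-author pair; 0.5 would be chance.")

tt = trend_test(res.replicates)
print(f"trend of AUC across pattern lengths: z = {tt.z:.2f}, p = {tt.p:.3g}")
print("-> positive z: longer patterns carry extra identifying information.")
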