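"""Classical RNGT indices on a synthetic cohort.

Redundancy measures unequal digit usage (0 = perfectly equal, 1 = one
digit only); the runs index is the variance of ascending-run lengths and
captures the tendency to count.
"""

import json

from rngfp import CohortSpec, generate_corpus, rngt_summary, rngt_table

corpus = generate_corpus(
    CohortSpec(n_subjects=20, sessions=2, third_session_subjects=0, master_seed=3)
)
table = rngt_table(corpus)
print(table.head(4).round(4).to_string(index=False))

summary = rngt_summary(table)
for name, block in summary["indices"].items():
    s1, s2 = block["session_1"], block["session_2"]
    print(f"{name}: session 1 {s1['mean']:.4f} +/- {s1['sd']:.4f}, "
          f"session 2 {s2['mean']:.4f} +/- {s2['sd']:.4f}, "
          f"paired t = {block['paired_t']['t']:.2f} (p = {block['paired_t']['p']:.3g})")
print("-> small positive redundancy and a nonzero runs variance are the"
      " classic signatures of human (non-mathematical) randomness.")
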