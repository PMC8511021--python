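"""Generate a synthetic human-RNG cohort and inspect its basic structure.

Each synthetic subject owns preferred and inhibited digit patterns and
reuses the preferred ones with small random edits, on top of a
near-uniform baseline with repetition suppression and a mild counting
tendency.
"""

import numpy as np

from rngfp import CohortSpec, generate_corpus, sample_profile, write_corpus

spec = CohortSpec(n_subjects=12, sessions=2, third_session_subjects=0,
                  sequence_length=300, master_seed=7)
corpus = generate_corpus(spec)
write_corpus(corpus, "cohort.tsv")

profile = sample_profile(spec, 0)
print(f"cohort: {len(corpus)} sequences from {len(corpus.subjects)} subjects")
print(f"subject {profile.subject_id} prefers {len(profile.preferred)} patterns, "
      f"e.g. {profile.preferred[-1][0]} (weight {profile.preferred[-1][1]:.2f})")

pooled = np.concatenate([s.as_array() for s in corpus])
freq = np.bincount(pooled, minlength=10)[1:] / len(pooled)
print("pooled digit frequencies:", np.round(freq, 3))
print("-> roughly 1/9 = 0.111 per digit: individual pattern reuse leaves the"
      " cohort-level digit marginals close to uniform (deviations shrink as"
      " the cohort grows), as in real RNG-task cohorts.")
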