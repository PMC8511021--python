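"""Which patterns carry a person's fingerprint: preferences or inhibitions?

For every subject, all 729 length-3 patterns are ranked from her rarest
(ordinal 1) to her most prevalent (ordinal 729) by session-1 scores.
At each ordinal, the within-subject score difference (session 1 vs 2)
is compared with the between-subject difference (her session 1 vs other
subjects); the gap delta = between - within measures how person-specific
patterns of that prevalence rank are.
"""

from rngfp import (
    CohortSpec,
    Corpus,
    band_top_patterns,
    default_bands,
    enumerate_patterns,
    generate_corpus,
    individuality_curve,
    ordinal_ranks,
    score_matrix,
)

import numpy as np
import pandas as pd

corpus = generate_corpus(
    CohortSpec(n_subjects=20, sessions=2, third_session_subjects=0, master_seed=5)
)
space = enumerate_patterns(3)  # full space, adjacent repeats included


def session_scores(session):
    df = score_matrix(Corpus([s for s in corpus if s.session == session]), space)
    df.index = df.index.get_level_values("subject_id")
    return df


s1, s2 = session_scores(1), session_scores(2)
curve = individuality_curve(s1, s2.loc[s1.index], space).table
for name, sl in [("rarest 300", slice(0, 300)), ("middle", slice(330, 600)),
                 ("most preferred 30", slice(699, 729))]:
    print(f"delta ({name} ordinals): {curve['delta'].iloc[sl].mean():.5f}")
print("-> delta elevated at BOTH ends: individual inhibitions (rare end) and"
      " individual preferences (common end) both carry the fingerprint.")

ranks = pd.DataFrame(
    np.vstack([ordinal_ranks(s1.loc[sid].to_numpy(), space) for sid in s1.index]),
    index=s1.index, columns=space.labels,
)
top = band_top_patterns(ranks, space, bands=default_bands())
print("most frequent 'universal exception' patterns:",
      [p for p, _ in top["universal_exceptions"]])
print("-> same-digit triplets: patterns nobody produces in a 'random' series.")
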