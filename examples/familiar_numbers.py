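"""Are personally familiar numbers over-represented in a person's sequence?

For each subject, length-3 subpatterns of her familiar number (e.g. a
birthdate) are scored in her own sequence and compared with the same
patterns' prevalence in other subjects' sequences; a one-sample t test
across subjects asks whether the average own-minus-others difference
departs from zero.  Run once on a null cohort (familiar numbers
unrelated to production) and once with planted over-emission.
"""

from rngfp import (
    CohortSpec,
    Corpus,
    enumerate_patterns,
    familiar_pattern_test,
    generate_corpus,
    generate_familiar,
    score_matrix,
)

space = enumerate_patterns(3)


def run(label, boost):
    spec = CohortSpec(n_subjects=15, sessions=1, third_session_subjects=0,
                      sequence_length=300, familiar_boost=boost,
                      familiar_style="random", master_seed=11)
    corpus = generate_corpus(spec)
    s1 = score_matrix(Corpus([s for s in corpus if s.session == 1]), space)
    s1.index = s1.index.get_level_values("subject_id")
    res = familiar_pattern_test(s1, generate_familiar(spec), space)["birthdate"]
    print(f"{label}: t({res.n_subjects - 1}) = {res.t:.2f}, p = {res.p:.3g} "
          f"(KS normality D = {res.ks_d:.2f}, p = {res.ks_p:.2f})")


run("null (familiar numbers unrelated)", boost=0.0)
run("planted over-emission", boost=1.0)
print("-> a non-significant null and a clearly positive planted t show the"
      " test can separate an 'environmental' fingerprint from none.")
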