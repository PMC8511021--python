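import numpy as np
import pandas as pd
import pytest

from rngfp import (
    BandSpec,
    band_top_patterns,
    default_bands,
    enumerate_patterns,
    familiar_pattern_test,
    familiar_subpatterns,
    individuality_curve,
    ordinal_ranks,
    score_matrix,
)
from rngfp.corpus import Corpus, DigitSequence

SP1 = enumerate_patterns(1)
SP3 = enumerate_patterns(3)


class TestOrdinalRanks:
    def test_sorted_input(self):
        scores = np.linspace(0, 1, 9)
        assert list(ordinal_ranks(scores, SP1)) == list(range(1, 10))

    def test_tie_broken_lexicographically(self):
        scores = np.array([0.5, 0.2, 0.2, 0.9, 0.6, 0.7, 0.8, 0.95, 0.99])
        ranks = ordinal_ranks(scores, SP1)
        assert ranks[1] == 1 and ranks[2] == 2  # tied 0.2: pattern '2' before '3'

    def test_agrees_with_sort_oracle(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=len(SP3))
        ranks = ordinal_ranks(scores, SP3)
        order = sorted(range(len(scores)), key=lambda i: (scores[i], i))
        expected = np.empty(len(scores), dtype=int)
        expected[order] = np.arange(1, len(scores) + 1)
        np.testing.assert_array_equal(ranks, expected)

    def test_filtered_space_rejected(self):
        sp = enumerate_patterns(3, exclude_repeats=True)
        with pytest.raises(ValueError):
            ordinal_ranks(np.zeros(len(sp)), sp)


def _scores_df(corpus, session, space):
    df = score_matrix(
        Corpus([s for s in corpus if s.session == session]), space
    )
    df.index = df.index.get_level_values("subject_id")
    return df


class TestIndividualityCurve:
    def test_degenerate_identity_cohort(self):
        """Everyone produces the same sequence in both sessions: all zeros."""
        digits = tuple([1, 2, 3, 4, 5, 6, 7, 8, 9] * 4)
        seqs = [
            DigitSequence(sid, sess, digits)
            for sid in ("A", "B", "C")
            for sess in (1, 2)
        ]
        corpus = Corpus(sequences=seqs)
        s1 = _scores_df(corpus, 1, SP1)
        s2 = _scores_df(corpus, 2, SP1)
        curve = individuality_curve(s1, s2, SP1)
        np.testing.assert_allclose(curve.table["within"], 0, atol=1e-12)
        np.testing.assert_allclose(curve.table["between"], 0, atol=1e-12)
        np.testing.assert_allclose(curve.table["delta"], 0, atol=1e-12)

    def test_two_subject_hand_computed_fixture(self):
        """4-digit sequences, length-1 space; expected values worked by hand.

        Length-1 DLS terms are 1 for a matching window and 1/2 otherwise,
        so s(d, z) = 0.5 + 0.5*count(d)/4, from which the within/between
        tables below follow by direct arithmetic.
        """
        seqs = [
            DigitSequence("A", 1, (1, 1, 2, 3)),
            DigitSequence("A", 2, (1, 2, 2, 3)),
            DigitSequence("B", 1, (3, 3, 3, 9)),
            DigitSequence("B", 2, (9, 9, 1, 3)),
        ]
        corpus = Corpus(sequences=seqs)
        curve = individuality_curve(
            _scores_df(corpus, 1, SP1), _scores_df(corpus, 2, SP1), SP1
        )
        expected_within = [0.0625, 0, 0, 0, 0, 0, 0.0625, 0.0625, 0.1875]
        expected_between = [0.125, 0.0625, 0, 0, 0, 0.0625, 0.0625, 0.1875, 0.25]
        np.testing.assert_allclose(curve.table["within"], expected_within, atol=1e-12)
        np.testing.assert_allclose(curve.table["between"], expected_between, atol=1e-12)
        np.testing.assert_allclose(
            curve.table["delta"],
            np.array(expected_between) - np.array(expected_within),
            atol=1e-12,
        )

    def test_invariant_to_subject_relabeling(self):
        rng = np.random.default_rng(1)
        seqs = [
            DigitSequence(sid, sess, tuple(rng.integers(1, 10, 80).tolist()))
            for sid in ("A", "B", "C", "D")
            for sess in (1, 2)
        ]
        corpus = Corpus(sequences=seqs)
        s1, s2 = _scores_df(corpus, 1, SP1), _scores_df(corpus, 2, SP1)
        base = individuality_curve(s1, s2, SP1).table
        perm = ["C", "A", "D", "B"]
        shuffled = individuality_curve(s1.loc[perm], s2.loc[perm], SP1).table
        pd.testing.assert_frame_equal(base, shuffled)

    def test_misaligned_sessions_rejected(self):
        rng = np.random.default_rng(2)
        seqs = [
            DigitSequence(sid, sess, tuple(rng.integers(1, 10, 40).tolist()))
            for sid in ("A", "B")
            for sess in (1, 2)
        ]
        corpus = Corpus(sequences=seqs)
        s1, s2 = _scores_df(corpus, 1, SP1), _scores_df(corpus, 2, SP1)
        with pytest.raises(ValueError):
            individuality_curve(s1, s2.iloc[::-1], SP1)


class TestBands:
    def test_default_band_layout(self):
        bands = default_bands(729)
        names = [b[0] for b in bands.bands]
        assert names[0] == "universal_exceptions"
        assert bands.bands[0][1:] == (1, 10)
        assert bands.bands[-1][1:] == (700, 729)

    def test_invalid_band_spec(self):
        with pytest.raises(ValueError):
            BandSpec(bands=(("x", 5, 2),))
        with pytest.raises(ValueError):
            BandSpec(bands=(("x", 1, 2), ("x", 3, 4)))

    def test_constructed_certainty(self):
        """All subjects rank the same patterns lowest: those dominate band [1,10]."""
        n_sub, n_pat = 4, 9
        ranks = pd.DataFrame(
            np.tile(np.arange(1, n_pat + 1), (n_sub, 1)),
            index=[f"S{i}" for i in range(n_sub)],
            columns=SP1.labels,
        )
        top = band_top_patterns(
            ranks, SP1, bands=BandSpec(bands=(("low", 1, 3),)), top_k=5
        )
        assert top["low"] == [("1", 4), ("2", 4), ("3", 4)]  # no padding past band

    def test_top_k_boundary(self):
        ranks = pd.DataFrame(
            [np.arange(1, 10)], index=["S0"], columns=SP1.labels
        )
        top = band_top_patterns(
            ranks, SP1, bands=BandSpec(bands=(("one", 1, 1),)), top_k=5
        )
        assert top["one"] == [("1", 1)]


class TestFamiliar:
    def test_subpattern_extraction_drops_zeros(self):
        # '10203' -> cleaned '123' -> one pattern
        assert familiar_subpatterns("10203") == [(1, 2, 3)]
        assert familiar_subpatterns("1231") == [(1, 2, 3), (2, 3, 1)]
        assert familiar_subpatterns("11") == []

    def test_deduplication(self):
        assert familiar_subpatterns("123123123") == [
            (1, 2, 3), (2, 3, 1), (3, 1, 2),
        ]

    def test_too_few_subjects_rejected(self):
        rng = np.random.default_rng(3)
        seqs = [
            DigitSequence(sid, 1, tuple(rng.integers(1, 10, 120).tolist()))
            for sid in ("A", "B")
        ]
        s1 = _scores_df(Corpus(sequences=seqs), 1, SP3)
        with pytest.raises(ValueError):
            familiar_pattern_test(s1, [("A", "birthdate", "1211990")], SP3)

    def test_returns_per_kind_results(self):
        rng = np.random.default_rng(4)
        seqs = [
            DigitSequence(f"S{i}", 1, tuple(rng.integers(1, 10, 200).tolist()))
            for i in range(8)
        ]
        s1 = _scores_df(Corpus(sequences=seqs), 1, SP3)
        fam = [(f"S{i}", "birthdate", f"{rng.integers(1, 29):02d}121985") for i in range(8)]
        res = familiar_pattern_test(s1, fam, SP3)
        assert set(res) == {"birthdate"}
        r = res["birthdate"]
        assert r.n_subjects == 8
        assert np.isfinite(r.t) and 0 <= r.p <= 1
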