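import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rngfp import (
    dl_distance,
    enumerate_patterns,
    exact_count_vector,
    exact_pattern_count,
    pattern_score,
    score_matrix,
    score_vector,
)
from rngfp._kernels import _score_kernel_numpy, score_all_patterns
from rngfp.corpus import Corpus, DigitSequence

from oracles import osa_recursive

digit_strings = st.lists(st.integers(1, 9), min_size=0, max_size=8).map(tuple)


class TestDLDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("123", "123", 0),
            ("2169", "2196", 1),  # one adjacent transposition
            ("1234", "5678", 4),  # four substitutions
            ("31", "123", 3),  # OSA: no edits inside a transposed block
            ("", "123", 3),
            ("1", "", 1),
        ],
    )
    def test_known_cases(self, a, b, expected):
        assert dl_distance(a, b) == expected

    def test_exhaustive_against_recursive_oracle(self):
        """All pairs of strings of length <= 4 over a 3-symbol alphabet."""
        strings = [
            t
            for L in range(5)
            for t in itertools.product((1, 2, 3), repeat=L)
        ]
        for a in strings:
            for b in strings:
                assert dl_distance(a, b) == osa_recursive(a, b)

    @settings(max_examples=200, deadline=None)
    @given(digit_strings, digit_strings)
    def test_symmetry_and_identity(self, a, b):
        d = dl_distance(a, b)
        assert d == dl_distance(b, a)
        assert (d == 0) == (a == b)
        assert d <= max(len(a), len(b))

    def test_triangle_inequality_sweep(self):
        """Exhaustive length <= 3 sweep over a 3-symbol alphabet.

        OSA can violate the triangle inequality in corner cases; any
        violating triples are recorded and checked to be of the known
        form (distance exceeding the sum by a bounded amount) rather
        than asserted away.
        """
        strings = [
            t for L in range(4) for t in itertools.product((1, 2, 3), repeat=L)
        ]
        d = {
            (a, b): dl_distance(a, b) for a in strings for b in strings
        }
        violations = []
        for a in strings:
            for b in strings:
                for c in strings:
                    if d[(a, c)] > d[(a, b)] + d[(b, c)]:
                        violations.append((a, b, c))
        for a, b, c in violations:
            assert d[(a, c)] <= d[(a, b)] + d[(b, c)] + 1


class TestPatternSpace:
    @pytest.mark.parametrize(
        "n,exclude,expected",
        [(1, False, 9), (3, False, 729), (3, True, 576), (2, True, 72)],
    )
    def test_sizes(self, n, exclude, expected):
        assert len(enumerate_patterns(n, exclude)) == expected

    def test_lexicographic_and_deterministic(self):
        sp = enumerate_patterns(2)
        assert sp.patterns[0] == (1, 1)
        assert sp.patterns[-1] == (9, 9)
        assert list(sp.patterns) == sorted(sp.patterns)
        assert sp.patterns == enumerate_patterns(2).patterns

    def test_repeat_exclusion_removes_adjacent_equal(self):
        sp = enumerate_patterns(3, exclude_repeats=True)
        for p in sp.patterns:
            assert p[0] != p[1] and p[1] != p[2]

    @pytest.mark.parametrize("n", [0, 7])
    def test_out_of_range(self, n):
        with pytest.raises(ValueError):
            enumerate_patterns(n)


class TestPatternScore:
    @pytest.mark.parametrize(
        "m,z,expected",
        [
            ((1,), [1, 1, 1], 1.0),
            ((2,), [1, 1, 1], 0.5),
            ((1, 2), [1, 2, 1, 2], 0.625),
        ],
    )
    def test_analytic_cases(self, m, z, expected):
        assert pattern_score(m, z) == pytest.approx(expected, abs=1e-15)

    def test_pattern_longer_than_sequence(self):
        with pytest.raises(ValueError):
            pattern_score((1, 2, 3), [1, 2])

    def test_values_in_unit_interval(self):
        rng = np.random.default_rng(0)
        z = rng.integers(1, 10, 50).tolist()
        sp = enumerate_patterns(2)
        v = score_vector(z, sp)
        assert np.all(v >= 0) and np.all(v <= 1)

    def test_exact_count_examples(self):
        assert exact_pattern_count((1, 2), [1, 2, 1, 2]) == pytest.approx(0.5)
        assert exact_pattern_count((3, 4), [1, 2, 1, 2]) == 0.0


class TestScoreVector:
    def test_matches_naive_loop(self):
        rng = np.random.default_rng(3)
        z = rng.integers(1, 10, 120).tolist()
        for n in (1, 2):
            sp = enumerate_patterns(n)
            fast = score_vector(z, sp)
            naive = np.array([pattern_score(p, z) for p in sp.patterns])
            np.testing.assert_allclose(fast, naive, atol=1e-12, rtol=0)

    def test_dimension_matches_space(self):
        z = [1, 2, 3, 4, 5]
        for n, excl in [(1, False), (2, True), (3, False)]:
            sp = enumerate_patterns(n, excl)
            assert score_vector(z, sp).shape == (len(sp),)

    def test_pure_function_of_digits(self):
        digits = tuple(np.random.default_rng(5).integers(1, 10, 40).tolist())
        sp = enumerate_patterns(2)
        a = score_vector(DigitSequence("A", 1, digits), sp)
        b = score_vector(DigitSequence("ZZZ", 9, digits), sp)
        np.testing.assert_array_equal(a, b)

    def test_length1_affine_relation(self):
        """s_i = 0.5 + 0.5 * c_i for length-1 patterns (d in {0,1})."""
        rng = np.random.default_rng(11)
        z = rng.integers(1, 10, 300).tolist()
        sp = enumerate_patterns(1)
        s = score_vector(z, sp)
        c = exact_count_vector(z, sp)
        np.testing.assert_allclose(s, 0.5 + 0.5 * c, atol=1e-12, rtol=0)

    def test_numpy_fallback_matches_numba_path(self):
        rng = np.random.default_rng(9)
        z = rng.integers(1, 10, 80)
        sp = enumerate_patterns(3, exclude_repeats=True)
        wins = np.lib.stride_tricks.sliding_window_view(z.astype(np.int8), 3)
        uniq, counts = np.unique(wins, axis=0, return_counts=True)
        via_dispatch = score_all_patterns(sp.as_array(), uniq, counts.astype(float))
        out = np.empty(len(sp))
        inv = 1.0 / (1.0 + np.arange(4, dtype=float))
        _score_kernel_numpy(
            sp.as_array().astype(np.int8),
            uniq.astype(np.int8),
            counts.astype(float),
            inv,
            out,
        )
        np.testing.assert_allclose(via_dispatch, out, atol=1e-12, rtol=0)


class TestScoreMatrix:
    def test_shape_and_labels(self, uniform_corpus):
        sp = enumerate_patterns(1)
        m = score_matrix(uniform_corpus, sp)
        assert m.shape == (len(uniform_corpus), 9)
        assert list(m.columns) == [str(d) for d in range(1, 10)]

    def test_exact_method(self):
        corpus = Corpus(
            sequences=[DigitSequence("A", 1, (1, 2, 1, 2))]
        )
        sp = enumerate_patterns(2)
        m = score_matrix(corpus, sp, method="exact")
        assert m.loc[("A", 1), "12"] == pytest.approx(0.5)

    def test_unknown_method(self, uniform_corpus):
        with pytest.raises(ValueError):
            score_matrix(uniform_corpus, enumerate_patterns(1), method="fuzzy")
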