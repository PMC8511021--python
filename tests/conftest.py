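import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from rngfp import CohortSpec, Corpus, DigitSequence, generate_corpus


@pytest.fixture(scope="session")
def small_cohort() -> Corpus:
    """Default-parameter synthetic cohort, acceptance scale (30 subjects)."""
    spec = CohortSpec(
        n_subjects=30, sessions=2, third_session_subjects=0, master_seed=42
    )
    return generate_corpus(spec)


@pytest.fixture(scope="session")
def null_cohort() -> Corpus:
    """Exchangeable cohort: every subject runs the identical shared profile."""
    spec = CohortSpec(
        n_subjects=30,
        sessions=2,
        third_session_subjects=0,
        individuality_strength=0.0,
        master_seed=42,
    )
    return generate_corpus(spec)


@pytest.fixture()
def uniform_corpus() -> Corpus:
    """IID-uniform digit corpus: 20 subjects x 2 sessions x 300 digits."""
    rng = np.random.default_rng(7)
    seqs = [
        DigitSequence(f"U{i:02d}", sess, tuple(rng.integers(1, 10, 300).tolist()))
        for i in range(20)
        for sess in (1, 2)
    ]
    return Corpus(sequences=seqs)
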