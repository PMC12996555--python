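import numpy as np
import pytest

import strokeprosody as sp


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny two-per-cell cohort shared by pipeline-shape tests."""
    return sp.make_cohort(sp.CohortSpec(n_per_cell=2, seed=7))


@pytest.fixture(scope="session")
def small_pairs(small_cohort):
    return sp.pairs_from_cohort(small_cohort)


@pytest.fixture(scope="session")
def clean_vowel():
    """Noiseless, jitter-free sustained vowel with ground truth."""
    spec = sp.VowelSpec(f0=120.0, formants=(730, 1090, 2440), duration=0.8)
    return sp.synthesize_vowel(spec, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
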