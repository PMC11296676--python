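import numpy as np
import pytest

from aerd_phenotyper import (
    CorpusConfig,
    default_aerd_ruleset,
    default_lexicon,
    generate_cohort,
)
from aerd_phenotyper.features import FEATURES


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def ruleset():
    return default_aerd_ruleset()


@pytest.fixture(scope="session")
def small_cohort(lexicon):
    """A small seeded corpus shared across round-trip tests."""
    config = CorpusConfig(n_positive=15, n_negative=15, seed=11)
    documents, profiles = generate_cohort(config, lexicon)
    return documents, profiles


def make_vector(**counts):
    """Full 7-feature count dict with unspecified features at zero."""
    base = dict.fromkeys(FEATURES, 0)
    base.update(counts)
    return base


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
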