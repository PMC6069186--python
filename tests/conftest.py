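import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from cvescreen import ScoringScheme, make_probes, make_reference_library


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def scheme():
    """Default scheme used by the screen."""
    return ScoringScheme()


@pytest.fixture(scope="session")
def small_scheme():
    """Lower reporting threshold for short synthetic peptides."""
    return ScoringScheme(min_score=30)


@pytest.fixture(scope="session")
def tiny_library():
    """A small structured reference library (short peptides, 2 per group)."""
    return make_reference_library(seed=11, rep_length=80, cap_length=90, n_per_group=2)


@pytest.fixture(scope="session")
def tiny_probes(tiny_library):
    return make_probes(tiny_library)
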