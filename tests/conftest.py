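import numpy as np
import pytest

from semfi import INDICATORS
from semfi.synthetic import DEFAULT_LOADINGS, SyntheticSpec, generate

#: Standardized loadings used as simulation truth throughout the suite.
TRUTH_LOADINGS = np.array([DEFAULT_LOADINGS[ind] for ind in INDICATORS])


@pytest.fixture(scope="session")
def default_table():
    """Full-design synthetic dataset with age/depth cell effects."""
    return generate(SyntheticSpec(seed=7))


@pytest.fixture(scope="session")
def homogeneous_table():
    """Pure factor-model draws (no cell effects), n = 500."""
    return generate(SyntheticSpec.homogeneous(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
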