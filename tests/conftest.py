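import numpy as np
import pytest

from nabiassim import build_reference_marginals, canonical_items


@pytest.fixture(scope="session")
def items():
    return canonical_items()


@pytest.fixture(scope="session")
def reference_marginals():
    return build_reference_marginals()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
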