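import numpy as np
import pytest

from scdunet import PhantomSpec, generate_case


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_case():
    """One default-spec phantom, shared across read-only tests."""
    return generate_case(PhantomSpec(), seed=7)
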