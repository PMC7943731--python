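import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom64():
    from deeppat.phantom_forge import generate_phantom

    return generate_phantom(64, 3, 42)


@pytest.fixture(scope="session")
def small_phantoms():
    """Six 16x16 phantoms for fast training-plumbing tests."""
    from deeppat.phantom_forge import generate_phantom

    return [generate_phantom(16, 1, 100 + i) for i in range(6)]
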