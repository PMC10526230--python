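import numpy as np
import pytest

from hsnet3d import PhantomConfig, generate_arrays


@pytest.fixture(scope="session")
def phantom_config():
    return PhantomConfig()


@pytest.fixture(scope="session")
def phantom_batch(phantom_config):
    """200 default-config phantoms shared by the discriminability checks."""
    X, table, Y = generate_arrays(200, phantom_config, seed=20240915)
    return X, table, Y


@pytest.fixture(scope="session")
def tiny_volumes():
    """A handful of small random volumes for plumbing tests."""
    rng = np.random.default_rng(0)
    X = rng.normal(size=(8, 16, 16, 16)).astype(np.float32)
    Y = rng.integers(0, 2, size=(8, 6))
    return X, Y
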