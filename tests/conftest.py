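import numpy as np
import pytest

from kinetrf import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small default-condition corpus shared by unit tests."""
    return generate_dataset(GeneratorConfig(n_files=2, duration_s=45, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
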