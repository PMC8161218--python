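import numpy as np
import pytest

from etis import GeneratorConfig, generate_dataset, generate_environment


@pytest.fixture(scope="session")
def barn_env():
    """A mid-sized synthetic climate table with default study conditions."""
    return generate_environment(GeneratorConfig(n=2000, seed=11))


@pytest.fixture(scope="session")
def barn_dataset():
    """Environment plus physiology, default study conditions."""
    return generate_dataset(GeneratorConfig(n=2000, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
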