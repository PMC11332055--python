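import numpy as np
import pytest

from qcla.embedding import MockEncoder
from qcla.synthetic import GeneratorConfig, build_lexicons, generate_dataset


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """A scaled-down study: 40 authors, 60 readers, 12-word lexicons."""
    return GeneratorConfig(
        n_phase1=40, n_phase2=60, lexicon_size_per_emotion=12, seed=7
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_lexicons(small_config):
    return build_lexicons(small_config)


@pytest.fixture(scope="session")
def small_encoder(small_lexicons):
    return MockEncoder(lexicons=small_lexicons, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
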