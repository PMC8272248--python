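import numpy as np
import pytest

from aggfuse.synthetic import GeneratorConfig, generate


@pytest.fixture(scope="session")
def default_table():
    """One default synthetic study table (29 participants × 3 classes)."""
    return generate(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def separable_table():
    """A table with class means 10 within-SDs apart: essentially separable."""
    return generate(GeneratorConfig(seed=5, effect_scale=10.0, participant_sd=0.2))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
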