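import numpy as np
import pytest

from psyctrl import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def cohort():
    """Default-condition synthetic cohort (30 participants, 11 items)."""
    return generate_cohort(GeneratorConfig(seed=42))


@pytest.fixture(scope="session")
def noisefree_cohort():
    """Noise-free, discretized cohort: the one-step dynamics still generate it."""
    return generate_cohort(GeneratorConfig(seed=7, noise_sd=0.0))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
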