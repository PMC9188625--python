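import numpy as np
import pandas as pd
import pytest

from sesmap.simulate import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort shared by read-only tests (n=800, default structure)."""
    config = GeneratorConfig(n_participants=800, seed=11)
    cohort, truth, atlas = generate_cohort(config)
    return config, cohort, truth, atlas


@pytest.fixture(scope="session")
def factor_only_ses():
    """Large pure factor-model SES block (no brain signal, continuous)."""
    config = GeneratorConfig(
        n_participants=20_000,
        effect_scale=0.0,
        ordinal_bins=(0, 0, 0, 0, 0, 0),
        seed=7,
    )
    cohort, truth, atlas = generate_cohort(config)
    return config, cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
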