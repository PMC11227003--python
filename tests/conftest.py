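import numpy as np
import pytest

from agiwear import cohort as coh
from agiwear import pipeline as pl


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_config():
    """A small but fully featured cohort configuration."""
    return coh.SimConfig(n_patients=3, days_per_patient=2, seed=7, eda_hz=8.0)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return coh.generate_cohort(tiny_config)


@pytest.fixture(scope="session")
def tiny_result(tiny_config):
    """Preprocessed tiny cohort (streamed generation), shared across tests."""
    return pl.preprocess(tiny_config)
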