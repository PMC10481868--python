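import numpy as np
import pytest

from gazeflow import GeneratorConfig, generate_study


@pytest.fixture(scope="session")
def small_study():
    """A small but complete synthetic study shared across read-only tests."""
    cfg = GeneratorConfig(n_participants=4, trials_per_condition=4)
    return generate_study(cfg, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
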