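import numpy as np
import pytest

from soilrich.synthetic import FieldParams, generate_survey, simulate_richness


@pytest.fixture(scope="session")
def small_survey():
    """300-site synthetic survey with richness, shared across tests."""
    sites = generate_survey(n_sites=300, seed=11)
    truth = simulate_richness(sites, field=FieldParams(seed=11))
    return sites.assign(richness=truth.richness), truth


@pytest.fixture
def rng():
    return np.random.default_rng(42)
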