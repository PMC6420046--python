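import numpy as np
import pytest

from huntsurvey import SuperpopulationModel, generate_population


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def teal_model():
    """The reference hurdle model: 95.5% null bags, positive-part rate 7."""
    return SuperpopulationModel(p=0.955, lam=7.0)


@pytest.fixture(scope="session")
def small_population(teal_model):
    """A modest fixed population for Monte Carlo checks that do not need
    the full study size."""
    gen = np.random.default_rng(404)
    return generate_population(2000, teal_model, gen)
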