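import numpy as np
import pytest

from cordyflux import ToySpec, load_fixture_tables, make_toy_model


@pytest.fixture(scope="session")
def toy_model():
    """Default paper-like toy network (read-only within tests)."""
    return make_toy_model()


@pytest.fixture(scope="session")
def certificate(toy_model):
    return toy_model.annotations["certificate"]


@pytest.fixture()
def toy_model_copy(toy_model):
    """A mutable copy for tests that re-parameterize the model."""
    return toy_model.copy()


@pytest.fixture(scope="session")
def tables():
    return load_fixture_tables()


@pytest.fixture(scope="session")
def wt_producer_solutions(toy_model, certificate):
    """Canonical WT + producer scenario flux vectors (shared, expensive-ish)."""
    from cordyflux import Scenario, run_scenario

    wt = Scenario(name="wild_type", glucose_uptake=10.0, cordycepin_flux=0.0,
                  experimental_mu=certificate["mu_max_wt"])
    producer = Scenario(name="producer", glucose_uptake=10.0,
                        cordycepin_flux=certificate["producer"]["cordycepin"],
                        experimental_mu=certificate["producer"]["mu"])
    return run_scenario(toy_model, wt), run_scenario(toy_model, producer), wt, producer
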