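import numpy as np
import pytest

from msipm.config import SpeciesSpec, StudyConfig
from msipm.simulate import default_scenario, simulate_bundle


@pytest.fixture(scope="session")
def small_scenario():
    """A trimmed community (T=10) for fast end-to-end checks."""
    sc = default_scenario(T=10)
    return sc


@pytest.fixture(scope="session")
def default_bundle():
    """One default-scenario synthetic community, shared across tests."""
    sc = default_scenario()
    bundle, truth = simulate_bundle(sc, seed=202)
    return bundle, truth, sc


@pytest.fixture()
def rng():
    return np.random.default_rng(8675309)


@pytest.fixture(scope="session")
def single_species_config():
    """A one-species study (razorbill-like, d=2) used for tiny CJS/pop tests."""
    return StudyConfig(T=8, species=(SpeciesSpec("R", "razorbill", d=2),))
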