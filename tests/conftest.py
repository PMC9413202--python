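import numpy as np
import pytest

from pklump.physiology import default_physiology
from pklump.synthetic import DEFAULT_PROFILE, generate_matched_kinetics_drug, generate_panel


@pytest.fixture(scope="session")
def phys():
    return default_physiology()


@pytest.fixture(scope="session")
def matched_drug(phys):
    """Drug constructed so every NET tissue equilibrates at one rate."""
    return generate_matched_kinetics_drug(phys, k=0.5, route="oral")


@pytest.fixture(scope="session")
def panel(phys):
    """The deterministic 20-drug synthetic study panel."""
    return generate_panel(DEFAULT_PROFILE, 20, seed=0, phys=phys)


@pytest.fixture(scope="session")
def small_panel(phys):
    return generate_panel(DEFAULT_PROFILE, 6, seed=11, phys=phys)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
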