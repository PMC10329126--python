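import numpy as np
import pytest

from nbpvf import NBPVFParams, load_bundled_dataset, nbpvf_rvs

# the three parameter triples used throughout the simulation study
TABLE_TRIPLES = (
    NBPVFParams(0.6, 1.3, 0.9),
    NBPVFParams(1.1, 0.9, 1.3),
    NBPVFParams(1.0, 1.5, 1.2),
)


@pytest.fixture(scope="session")
def reactor_pumps():
    """Failure times of 23 secondary reactor pumps (transcribed fixture)."""
    return load_bundled_dataset("reactor_pumps")


@pytest.fixture(scope="session")
def electronic_machines():
    """Failure times per 1000 h of 50 electronic machines (transcribed fixture)."""
    return load_bundled_dataset("electronic_machines")


@pytest.fixture(scope="session")
def medium_sample():
    """A 200-point draw from (0.6, 1.3, 0.9), fixed seed, reused across tests."""
    return nbpvf_rvs(200, TABLE_TRIPLES[0], seed=1234)
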