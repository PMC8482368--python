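import pytest

from cometchem import H3_18_26, H4_4_17, enumerate_isotopologues, group_isobaric
from cometchem.simulator import default_h3_config, simulate_dataset


@pytest.fixture(scope="session")
def h3_species():
    return enumerate_isotopologues(H3_18_26)


@pytest.fixture(scope="session")
def h3_groups(h3_species):
    return group_isobaric(h3_species, charge=2, tol=0.005)


@pytest.fixture(scope="session")
def h3_by_id(h3_species):
    return {s.display_id: s for s in h3_species}


@pytest.fixture(scope="session")
def h4_species():
    return enumerate_isotopologues(H4_4_17)


@pytest.fixture(scope="session")
def h4_groups(h4_species):
    return group_isobaric(h4_species, charge=2, tol=0.005)


@pytest.fixture(scope="session")
def default_dataset():
    """The reference simulated two-site experiment (printed rates, seed 0)."""
    return simulate_dataset(default_h3_config())
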