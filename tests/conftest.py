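import logging

import pytest

import nephrosim as ns

logging.getLogger("nephrosim").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def mouse():
    return ns.load_species_parameters("mouse")


@pytest.fixture(scope="session")
def rat():
    return ns.load_species_parameters("rat")


@pytest.fixture(scope="session")
def human():
    return ns.load_species_parameters("human")


@pytest.fixture(scope="session")
def all_species(mouse, rat, human):
    return {"mouse": mouse, "rat": rat, "human": human}


@pytest.fixture(scope="session")
def dbdb_run(mouse):
    """Full-injury db/db trajectory shared across tests."""
    return ns.simulate_protocol(mouse, ns.dbdb_protocol(), horizon=24.0,
                                dt_out=0.25)


@pytest.fixture(scope="session")
def dbdb_unx_run(mouse):
    return ns.simulate_protocol(mouse, ns.dbdb_unx_protocol(), horizon=24.0,
                                dt_out=0.25)


@pytest.fixture(scope="session")
def wt_run(mouse):
    return ns.simulate_protocol(mouse, ns.wild_type_protocol(), horizon=24.0,
                                dt_out=0.5)
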