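import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from glycocg import ChainSpec, ForceFieldTables, build_topology, generate_initial_coords

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

ALL_LINKAGES = ("b12", "b13", "a14", "b14", "a16")


@pytest.fixture(scope="session")
def tables():
    return ForceFieldTables()


@pytest.fixture(scope="session")
def monomer_topology(tables):
    return build_topology(ChainSpec(n_residues=1, anomer="beta"), tables)


@pytest.fixture(scope="session")
def dimer_topologies(tables):
    return {
        lt: build_topology(ChainSpec(n_residues=2, linkage=lt), tables)
        for lt in ALL_LINKAGES
    }


@pytest.fixture(scope="session")
def octamer_topologies(tables):
    return {
        lt: build_topology(ChainSpec(n_residues=8, linkage=lt), tables)
        for lt in ALL_LINKAGES
    }


@pytest.fixture(scope="session")
def a14_octamer_conformation(octamer_topologies):
    return generate_initial_coords(octamer_topologies["a14"], seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
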