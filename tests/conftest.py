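import numpy as np
import pytest

from fibrilcap import group_layers
from fibrilcap.capping_dock import enumerate_binding_sites, graft_scaffold
from fibrilcap.fibril_model import assign_secondary_structure
from fibrilcap.synthetic_fixtures import (
    FibrilSpec,
    make_complementary_capper,
    make_ideal_fibril,
)


@pytest.fixture(scope="session")
def fibril():
    """Noiseless single-protofilament ground-truth fibril."""
    return make_ideal_fibril(FibrilSpec())


@pytest.fixture(scope="session")
def model(fibril):
    return fibril[0]


@pytest.fixture(scope="session")
def truth(fibril):
    return fibril[1]


@pytest.fixture(scope="session")
def assembly(model):
    return group_layers(model)


@pytest.fixture(scope="session")
def plus_sites(assembly):
    tip_ss = assign_secondary_structure(assembly.tip_layer(0, "plus"))
    return enumerate_binding_sites(tip_ss, window=6, end="plus")


@pytest.fixture(scope="session")
def capper_pose(assembly, truth, plus_sites):
    """Perfect complementary capper grafted on the first plus-end site."""
    site = plus_sites[0]
    capper = make_complementary_capper(site, truth)
    return graft_scaffold(capper, 0, site, assembly, "capper0")
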