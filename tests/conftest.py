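import pytest

from mtencode.hexagon import KinaseHexagon
from mtencode.lattice import LatticeSpec, build_lattice, neighborhood_patch


@pytest.fixture(scope="session")
def lattice_A():
    return build_lattice(LatticeSpec(lattice_type="A", n_dimer_rings=21))


@pytest.fixture(scope="session")
def lattice_B():
    return build_lattice(LatticeSpec(lattice_type="B", n_dimer_rings=24))


@pytest.fixture(scope="session")
def patch_A(lattice_A):
    return neighborhood_patch(lattice_A, lattice_A.site(6, 10))


@pytest.fixture(scope="session")
def patch_B(lattice_B):
    return neighborhood_patch(lattice_B, lattice_B.site(6, 12))


@pytest.fixture()
def hexagon():
    return KinaseHexagon.regular()
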