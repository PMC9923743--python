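import numpy as np
import pytest

from diabatmd.fixtures import PCETToySpec, make_pcet_toy, make_small_molecule
from diabatmd.hamiltonian import gaussian_integrals
from diabatmd.scf import SCFConfig, scf_solve


@pytest.fixture(scope="session")
def h2():
    geometry, basis = make_small_molecule("h2")
    return geometry, basis, gaussian_integrals(geometry, basis)


@pytest.fixture(scope="session")
def h2_ground(h2):
    _, _, ints = h2
    return scf_solve(ints, 1, 1, mode="restricted",
                     config=SCFConfig(tol_commutator=1e-10, tol_energy=1e-12))


@pytest.fixture(scope="session")
def toy():
    """The seeded PCET toy with its polarizable environment."""
    return make_pcet_toy(PCETToySpec(seed=1))


@pytest.fixture(scope="session")
def gas_toy():
    """Environment-free variant of the PCET toy."""
    return make_pcet_toy(PCETToySpec(seed=1, env_n_sites=0))


@pytest.fixture(scope="session")
def tight():
    return SCFConfig(tol_commutator=1e-10, tol_energy=1e-12)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
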