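import numpy as np
import pytest

from sumd.core import BindingSiteSpec, State, Topology
from sumd.systems import FixtureSpec, make_system


def simple_topology(
    n_target: int = 2,
    n_ligand: int = 1,
    charge_t: float = -1.0,
    charge_l: float = 1.0,
    eps: float = 0.2,
    sigma: float = 3.0,
    mass: float = 10.0,
) -> Topology:
    n = n_target + n_ligand
    return Topology(
        atom_id=np.arange(1, n + 1),
        name=np.array([f"T{i}" for i in range(n_target)]
                      + [f"L{i}" for i in range(n_ligand)], object).astype(str),
        group_id=np.concatenate([np.arange(n_target), np.full(n_ligand, n_target)]),
        group_name=np.array([f"TGT{i + 1}" for i in range(n_target)]
                            + ["LIG1"] * n_ligand, object).astype(str),
        role=np.array(["target"] * n_target + ["ligand"] * n_ligand,
                      object).astype(str),
        charge=np.concatenate([np.full(n_target, charge_t),
                               np.full(n_ligand, charge_l)]),
        lj_epsilon=np.full(n, eps),
        lj_sigma=np.full(n, sigma),
        mass=np.full(n, mass),
    )


def state_at(positions, seed=None) -> State:
    positions = np.asarray(positions, float)
    s = State(positions, np.zeros_like(positions))
    if seed is not None:
        s.rng_state = np.random.PCG64(seed).state
    return s


@pytest.fixture
def pair_topology() -> Topology:
    """One target atom and one ligand atom, parameterized."""
    return simple_topology(n_target=1, n_ligand=1)


@pytest.fixture(scope="session")
def funnel():
    """The standard funnel fixture: (topology, bound, start, site)."""
    return make_system(FixtureSpec())


@pytest.fixture(scope="session")
def funnel_topology(funnel) -> Topology:
    return funnel[0]


@pytest.fixture
def mock_system():
    """Small parameterized system + site for scripted-engine tests."""
    topo = simple_topology(n_target=4, n_ligand=2)
    target = np.array(
        [[0.0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3]], float
    )
    ligand = np.array([[30.0, 0, 0], [32.0, 0, 0]], float)
    state = state_at(np.vstack([target, ligand]), seed=0)
    site = BindingSiteSpec(group_ids=(0, 1, 2, 3))
    return topo, state, site
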