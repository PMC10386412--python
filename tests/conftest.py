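import numpy as np
import pytest

import phyloendemism as pe
from phyloendemism import synthetic_data as sd


@pytest.fixture
def toy_tree() -> pe.PhyloTree:
    """Three tips, one cherry: ((A:1,B:1):1,C:2); total length 5."""
    return pe.parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def toy_incidence() -> pe.IncidenceMatrix:
    """A in c1, B in both cells, C in c2."""
    return pe.IncidenceMatrix(
        ["A", "B", "C"],
        ["c1", "c2"],
        np.array([[1, 0], [1, 1], [0, 1]], dtype=bool),
    )


def random_instance(seed: int, n_tips: int = 12, n_cells: int = 20, p: float = 0.35):
    """A random tree plus random incidence with every cell occupied."""
    rng = np.random.default_rng(seed)
    tree = pe.parse_newick(sd.simulate_tree(n_tips, seed=seed))
    presence = rng.random((n_tips, n_cells)) < p
    for c in np.nonzero(~presence.any(axis=0))[0]:
        presence[rng.integers(n_tips), c] = True
    for s in np.nonzero(~presence.any(axis=1))[0]:
        presence[s, rng.integers(n_cells)] = True
    incidence = pe.IncidenceMatrix(
        tree.tip_labels, [f"c{i:03d}" for i in range(n_cells)], presence
    )
    return tree, incidence


@pytest.fixture(scope="session")
def small_sim() -> sd.SimulatedData:
    """One small synthetic dataset shared across tests."""
    return sd.simulate_dataset(sd.small_config(seed=11))
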