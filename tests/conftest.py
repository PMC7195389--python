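import numpy as np
import pytest

from interdom.structures import Structure
from interdom.synthetic import make_toy_multidomain, simulate_crosslinks


@pytest.fixture(scope="session")
def toy_closed():
    return make_toy_multidomain(seed=1)


@pytest.fixture(scope="session")
def toy_open():
    return make_toy_multidomain(seed=1, conformation="open")


@pytest.fixture(scope="session")
def toy_links(toy_closed):
    csv, truth = simulate_crosslinks(toy_closed, n_true=12, n_false=2, seed=1)
    return csv, truth


def ca_structure(coords, resnums=None):
    """Build a Cα-only structure from raw coordinates (test helper)."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    n = len(coords)
    resnums = resnums if resnums is not None else list(range(1, n + 1))
    return Structure(
        chain=np.full(n, "A"),
        resnum=np.array(resnums),
        resname=np.full(n, "GLY"),
        atomname=np.full(n, "CA"),
        element=np.full(n, "C"),
        xyz=coords,
    )


@pytest.fixture
def make_ca_structure():
    return ca_structure
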