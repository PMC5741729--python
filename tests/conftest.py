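import numpy as np
import pytest

from fibrilsim import ModelParams, default_stiffness_values, make_profile
from fibrilsim.core import Fibril


@pytest.fixture(scope="session")
def params():
    """Shipped default parameters."""
    return ModelParams()


@pytest.fixture(scope="session")
def fast_params():
    """Short-duration parameters for cheap end-to-end runs."""
    return ModelParams(duration=60.0, restretch_duration=30.0)


@pytest.fixture
def profile():
    return make_profile(default_stiffness_values())


@pytest.fixture
def single_dimer(profile, params):
    """A fibril holding just the substrate-bound root dimer."""
    return Fibril(profile, frozenset(range(1, 16)), params)


def grow_fibril(fibril, n_attach, rng):
    """Grow a fibril by n random attachments (exposure forced, no mechanics)."""
    for _ in range(n_attach):
        perim = sorted(fibril.perimeter_molecules())
        mol = int(rng.choice(perim))
        nodes = [fibril.node_of(mol, p) for p in range(1, 31)]
        free = [n for n in nodes if fibril.cryptic[n] and not fibril.occupied[n]]
        if not free:
            continue
        node = int(rng.choice(free))
        fibril.exposed[node] = True
        fibril.attach_soluble_fn(mol, int(fibril.node_pos[node]))
    return fibril
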