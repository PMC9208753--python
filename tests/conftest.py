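import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles module

import paraspec as ps


@pytest.fixture(scope="session")
def lg():
    return ps.lg_model()


@pytest.fixture(scope="session")
def lg_gamma():
    return ps.lg_model(gamma_shape=1.0, n_categories=4)


@pytest.fixture(scope="session")
def poisson():
    return ps.poisson_model()


@pytest.fixture
def quartet_tree():
    return ps.parse_newick("((A:0.12,B:0.3):0.08,(C:0.25,D:0.1):0.15);")


@pytest.fixture
def small_simulation(quartet_tree):
    model = ps.random_reversible_model(11, gamma_shape=0.8, n_categories=2)
    sim = ps.evolve_alignment(quartet_tree, model, 12, seed=5)
    return sim, model
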