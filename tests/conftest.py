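import numpy as np
import pytest

from arborgen.synth import FixtureSpec, make_toy_tree, make_reference_population


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def y_tree():
    return make_toy_tree("Y", 10.0)


@pytest.fixture
def chain_tree():
    return make_toy_tree("chain", 10.0, n=4)


@pytest.fixture
def binary_tree():
    return make_toy_tree("binary", 10.0, depth=3)


@pytest.fixture(scope="session")
def small_population():
    """A small grown population with known decaying rate (session-cached)."""
    spec = FixtureSpec(K=40, delta=0.025, seed=2024)
    return make_reference_population(spec, 10)
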