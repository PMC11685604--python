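import numpy as np
import pytest

from deepstain3d import phantoms


@pytest.fixture(scope="session")
def benchmark_phantom():
    return phantoms.make_benchmark_phantom(tau_true=0.005, seed=0)


@pytest.fixture(scope="session")
def glom_phantom():
    return phantoms.make_glomerulus_phantom(seed=0)


@pytest.fixture(scope="session")
def prox_phantom():
    return phantoms.make_proximity_phantom(seed=0)


@pytest.fixture(scope="session")
def fiber_phantom_x():
    return phantoms.make_fiber_phantom(orientation=(0, 0, 1), snr=np.inf, seed=2)


def random_tree(rng, n_nodes=30, extent=20.0):
    """Random rooted tree with random 3D node positions (test helper)."""
    from deepstain3d.morphometry import TracedTree

    nodes = {1: rng.uniform(0, extent, 3)}
    parents: dict[int, int | None] = {1: None}
    for i in range(2, n_nodes + 1):
        parents[i] = int(rng.integers(1, i))
        nodes[i] = rng.uniform(0, extent, 3)
    return TracedTree(nodes, parents)
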