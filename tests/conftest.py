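import numpy as np
import pytest

from ictonet import CouplingMatrix, NodeParameters, NoiseSpec, SimulationConfig


@pytest.fixture
def params():
    """Default bistable operating point."""
    return NodeParameters(a=-1.0, b=2.0, c=-0.9, omega=1.0)


@pytest.fixture
def quiet():
    """Noise-free spec."""
    return NoiseSpec(sigma=0.0, seed=0)


@pytest.fixture
def short_config():
    """Short deterministic-friendly integration window for unit tests."""
    return SimulationConfig(dt=0.005, duration=10.0, init_mode="at_steady_state", seed=0)


@pytest.fixture
def single_node():
    return CouplingMatrix.uncoupled(1)


def random_binary_adjacency(n, p, rng):
    """Erdos-Renyi style symmetric 0/1 adjacency with zero diagonal."""
    a = (rng.random((n, n)) < p).astype(int)
    a = np.triu(a, k=1)
    return a + a.T
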