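import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from nmflp import Graph, PlantedSpec, generate_sbm
from nmflp.graph_io import normalize_attributes


@pytest.fixture
def triangle() -> Graph:
    return Graph(["1", "2", "3"], {(0, 1), (1, 2), (0, 2)})


@pytest.fixture
def path3() -> Graph:
    """Path graph 1 - 2 - 3."""
    return Graph(["1", "2", "3"], {(0, 1), (1, 2)})


@pytest.fixture
def star4() -> Graph:
    """Star with center c and leaves a, b, d."""
    return Graph(["c", "a", "b", "d"], {(0, 1), (0, 2), (0, 3)})


@pytest.fixture
def small_sbm():
    graph, attrs, z = generate_sbm(
        PlantedSpec(n=40, blocks=2, p_in=0.4, p_out=0.05, m=10,
                    attr_signal=0.9, seed=7))
    return graph, normalize_attributes(attrs), z


def random_instance(seed, n=12, m=6, k=3, density=0.3):
    """Random adjacency + normalized attributes + random positive factors."""
    rng = np.random.default_rng(seed)
    A = (rng.random((n, n)) < density).astype(float)
    A = np.triu(A, 1)
    A = A + A.T
    B = rng.random((m, n))
    B /= B.sum(axis=0, keepdims=True)
    return A, B
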