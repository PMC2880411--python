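import networkx as nx
import numpy as np
import pytest

from macronet.network import GraphState, NetworkConfig, build_regular_graph
from macronet.payoffs import InteractionMatrix, SelectionConfig

# the six figure-scale payoff/initial-condition settings (k=4, omega=0.01)
FIG_SETTINGS = {
    "fig2": (InteractionMatrix(1, 0, 0, 1), 0.99),
    "fig3": (InteractionMatrix(0, -0.5, 1, 0), 0.99),
    "fig4": (InteractionMatrix(0, 1, 1, 0), 0.99),
    "fig5": (InteractionMatrix(0, 1, 1, 0), 0.40),
    "fig6": (InteractionMatrix(0, -1, -2, 0), 0.99),
    "fig7": (InteractionMatrix(0, -1, -2, 0), 0.20),
}


@pytest.fixture(scope="session")
def small_graph():
    """Connected 4-regular graph on 20 vertices (seeded)."""
    return build_regular_graph(NetworkConfig(N=20, k=4, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_state(N: int, k: int, p: float, seed: int) -> GraphState:
    """Random regular graph with iid type labels (helper, not a fixture)."""
    g = build_regular_graph(NetworkConfig(N=N, k=k, seed=seed))
    r = np.random.default_rng(seed + 1)
    types = (r.random(N) < p).astype(np.int8)
    return GraphState(g, types, k)


@pytest.fixture(scope="session")
def weak_sel():
    return SelectionConfig(0.01)
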