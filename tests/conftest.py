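import numpy as np
import pandas as pd
import pytest

from riversem.causal_graph import CausalDiagram


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def chain_diagram():
    """X -> Z -> Y."""
    return CausalDiagram(["X", "Z", "Y"], [("X", "Z"), ("Z", "Y")])


@pytest.fixture
def gradient_community(rng):
    """A small community with one strong environmental gradient."""
    n_sites, n_taxa = 24, 12
    gradient = np.linspace(-1.5, 1.5, n_sites)
    b = rng.normal(0, 1.0, n_taxa)
    lam = np.exp(2.0 + np.outer(gradient, b))
    counts = rng.poisson(lam)
    return pd.DataFrame(
        counts,
        index=[f"s{i:02d}" for i in range(n_sites)],
        columns=[f"t{j:02d}" for j in range(n_taxa)],
    )


def random_dag(rng, n_nodes, p_edge=0.4, shuffle_order=True):
    """A random DAG: random topological order, independent edges."""
    names = [f"v{i}" for i in range(n_nodes)]
    order = list(rng.permutation(n_nodes)) if shuffle_order else list(range(n_nodes))
    arrows = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                arrows.append((names[order[i]], names[order[j]]))
    return CausalDiagram(names, arrows)
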