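import numpy as np
import pytest

from signko import FunctionalNetwork


@pytest.fixture
def frustrated_triangle() -> FunctionalNetwork:
    """Triangle whose edge signs admit no perfect Boolean assignment."""
    return FunctionalNetwork([("a", "b", 1), ("b", "c", 1), ("a", "c", -1)])


@pytest.fixture
def signlinear_net() -> FunctionalNetwork:
    """Fully satisfiable instance: sigma = {a:+1, b:+1, c:-1, d:+1}."""
    return FunctionalNetwork(
        [("a", "b", 1), ("a", "c", -1), ("b", "c", -1), ("b", "d", 1)]
    )


def random_functional_net(
    rng: np.random.Generator, n_genes: int, density: float
) -> FunctionalNetwork:
    """Random directed signed network with at least one edge."""
    genes = [f"g{i}" for i in range(n_genes)]
    edges = []
    for u in genes:
        for v in genes:
            if u != v and rng.random() < density:
                edges.append((u, v, 1 if rng.random() < 0.5 else -1))
    if not edges:
        edges.append((genes[0], genes[1], 1))
    return FunctionalNetwork(edges)
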