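import networkx as nx
import pytest

from homonet import SocietyConfig, generate_society


def two_cliques_bridge(k: int = 4) -> nx.Graph:
    """Two k-cliques joined by a single unit-weight bridge edge."""
    g = nx.Graph()
    for base in (0, k):
        for i in range(k):
            for j in range(i + 1, k):
                g.add_edge(base + i, base + j, weight=1)
    g.add_edge(0, k, weight=1)
    return g


@pytest.fixture(scope="session")
def homophilous_society():
    """Small society with strong planted language homophily."""
    cfg = SocietyConfig(
        n_agents=300, n_days=14, events_per_day=120, lang_homophily=0.9, seed=11
    )
    return generate_society(cfg)


@pytest.fixture(scope="session")
def content_society():
    """Single-language society with strong planted content homophily."""
    cfg = SocietyConfig(
        n_agents=150,
        n_days=14,
        events_per_day=80,
        content_homophily=3.0,
        language_props={"english": 1.0},
        seed=7,
    )
    return generate_society(cfg)
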