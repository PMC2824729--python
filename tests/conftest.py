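import networkx as nx
import pytest

from domprior.simulate import WorldConfig, generate_world


@pytest.fixture(scope="session")
def small_world():
    """A compact synthetic world reused by read-only tests."""
    return generate_world(WorldConfig(n_domains=80, n_proteins=120,
                                      n_planted=5, t_d=60, n_negatives=40,
                                      seed=11))


@pytest.fixture(scope="session")
def small_world_dir(tmp_path_factory):
    """The same compact world written to disk."""
    outdir = tmp_path_factory.mktemp("world")
    world = generate_world(
        WorldConfig(n_domains=80, n_proteins=120, n_planted=5, t_d=60,
                    n_negatives=40, seed=11),
        outdir,
    )
    return world


def relabeled(g: nx.Graph, prefix: str = "PF") -> nx.Graph:
    """Relabel integer nodes to domain-style string IDs."""
    return nx.relabel_nodes(g, {n: f"{prefix}{int(n):05d}" for n in g.nodes})


@pytest.fixture
def er_graph():
    """Seeded Erdős–Rényi graph with domain-style node labels."""
    def make(n: int = 30, p: float = 0.2, seed: int = 0) -> nx.Graph:
        return relabeled(nx.erdos_renyi_graph(n, p, seed=seed))
    return make
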