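import networkx as nx
import numpy as np
import pytest

from panresil.network import Network
from panresil.resilience import shannon_diversity


@pytest.fixture
def triangle():
    return Network.from_edges([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def path3():
    return Network.from_edges([("A", "B"), ("B", "C")])


@pytest.fixture
def star5():
    return Network.from_edges([("hub", f"leaf{i}") for i in range(4)])


def random_network(seed: int, n: int = 60, p: float = 0.08) -> Network:
    g = nx.fast_gnp_random_graph(n, p, seed=seed)
    return Network.from_networkx(g, name=f"gnp-{seed}")


def brute_force_curve(net: Network, order: list[str]) -> np.ndarray:
    """Independent oracle: recount components after each isolation.

    Rebuilds the surviving edge set from scratch at every step and
    labels components with networkx; isolated nodes count as size-1
    components and N stays the original node count.
    """
    n = net.n_nodes
    all_nodes = net.node_ids
    edges = net.edge_set()
    s_vals = [0.0] * (n + 1)
    removed: set[str] = set()
    for k in range(n + 1):
        g = nx.Graph()
        g.add_nodes_from(all_nodes)
        g.add_edges_from((u, v) for u, v in edges
                         if u not in removed and v not in removed)
        sizes = [len(c) for c in nx.connected_components(g)]
        s_vals[k] = shannon_diversity(sizes, n)
        if k < n:
            removed.add(order[k])
    return np.asarray(s_vals)


@pytest.fixture(scope="session")
def synth_default():
    """One synthetic instance at the default study conditions."""
    from panresil.mutations import gene_mutation_counts
    from panresil.synth import SynthConfig, synth_mutations, synth_network
    cfg = SynthConfig(seed=1)
    net, truth = synth_network(cfg)
    counts = gene_mutation_counts(synth_mutations(net, truth, cfg), net)
    return net, truth, counts
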