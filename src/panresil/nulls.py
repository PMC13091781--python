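"""Standard comparison networks matched to a reference interactome.

Four families are used as benchmarks: fully connected (FC), random
regular (RR), Erdős–Rényi (ER) and preferential-attachment scale-free
(SF).  RR/ER/FC are matched to the reference density (RR via the
rounded average degree, ER via the link probability); the SF model uses
a fixed attachment count m (the interactome benchmark uses m = 6,
chosen as the best degree-distribution fit, not a density match).  The
FC benchmark is conventionally run at half the reference size to keep
the quadratic edge count within memory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .network import Network, network_summary
from .resilience import RemovalSchedule

logger = logging.getLogger(__name__)

__all__ = [
    "NullConfig",
    "make_complete",
    "make_random_regular",
    "make_erdos_renyi",
    "make_scale_free",
    "build_null",
    "matched_null_configs",
    "degree_matched_schedule",
]

MODELS = ("fully_connected", "random_regular", "erdos_renyi", "scale_free")


@dataclass
class NullConfig:
    """Parameters of one standard network model.

    Exactly the parameter matching the model is meaningful: ``d`` for
    random_regular, ``p`` for erdos_renyi, ``m`` for scale_free.
    """
    model: str
    n_nodes: int
    d: int | None = None
    p: float | None = None
    m: int | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.model == "random_regular":
            if self.d is None or (self.n_nodes * self.d) % 2 or self.d >= self.n_nodes:
                raise ValueError("random_regular needs d < n with n*d even")
        if self.model == "erdos_renyi" and not (self.p and 0 < self.p < 1):
            raise ValueError("erdos_renyi needs 0 < p < 1")
        if self.model == "scale_free" and not (self.m and 1 <= self.m < self.n_nodes):
            raise ValueError("scale_free needs 1 <= m < n")


def make_complete(n: int, max_edges: int = 200_000_000) -> Network:
    """Complete graph on n nodes; errors past the memory budget with a
    hint to halve n (the conventional FC benchmark size)."""
    return Network.complete(n, name=f"FC(n={n})", max_edges=max_edges)


def make_random_regular(n: int, d: int, seed: int | None = None) -> Network:
    """Simple random d-regular graph (configuration/pairing model)."""
    if (n * d) % 2:
        raise ValueError(f"no d-regular graph on n={n}, d={d}: n*d is odd")
    g = nx.random_regular_graph(d, n, seed=seed)
    return Network.from_networkx(g, name=f"RR(n={n},d={d})")


def make_erdos_renyi(n: int, p: float, seed: int | None = None) -> Network:
    """G(n, p): each unordered pair is an edge independently with prob p."""
    if not 0 < p < 1:
        raise ValueError("need 0 < p < 1")
    g = nx.fast_gnp_random_graph(n, p, seed=seed)
    return Network.from_networkx(g, name=f"ER(n={n},p={p:g})")


def make_scale_free(n: int, m: int, seed: int | None = None) -> Network:
    """Barabási–Albert graph: growth from a star on m+1 nodes, each new
    node attaching m edges preferentially; edge count m(n-m)."""
    if not 1 <= m < n:
        raise ValueError("need 1 <= m < n")
    g = nx.barabasi_albert_graph(n, m, seed=seed)
    return Network.from_networkx(g, name=f"SF(n={n},m={m})")


def build_null(config: NullConfig, seed: int | None = None) -> Network:
    """Instantiate one network from a :class:`NullConfig`."""
    s = seed if seed is not None else config.seed
    if config.model == "fully_connected":
        return make_complete(config.n_nodes)
    if config.model == "random_regular":
        return make_random_regular(config.n_nodes, config.d, seed=s)
    if config.model == "erdos_renyi":
        return make_erdos_renyi(config.n_nodes, config.p, seed=s)
    return make_scale_free(config.n_nodes, config.m, seed=s)


def matched_null_configs(reference: Network, seed: int | None = None,
                         m_default: int = 6,
                         halve_fc: bool = True) -> list[NullConfig]:
    """The four benchmark configs matched to a reference network.

    FC at half the reference size (full size behind ``halve_fc=False``),
    RR at d = round(average degree) (decremented when n*d would be odd),
    ER at p = reference density, SF at ``min(m_default, n // 2)``.
    """
    s = network_summary(reference)
    n = s.n_nodes
    d = int(round(s.avg_degree))
    if (n * d) % 2:
        d -= 1
        logger.info("matched_null_configs: decremented RR degree to %d "
                    "for feasibility (n*d must be even)", d)
    m = min(m_default, n // 2)
    return [
        NullConfig("fully_connected", max(2, n // 2 if halve_fc else n), seed=seed),
        NullConfig("random_regular", n, d=d, seed=seed),
        NullConfig("erdos_renyi", n, p=s.density, seed=seed),
        NullConfig("scale_free", n, m=m, seed=seed),
    ]


def degree_matched_schedule(net: Network, reference_order,
                            seed: int | None = None) -> RemovalSchedule:
    """Degree-matched random control order.

    For each position of ``reference_order`` a node is sampled uniformly
    without replacement among net nodes whose intact-network degree
    equals the reference node's degree; an exhausted degree class falls
    back to the nearest non-empty class (logged).  The remaining nodes
    are appended in uniform random order so the schedule is a full
    permutation.
    """
    rng = np.random.default_rng(seed)
    deg = net.degrees()
    nodes = net.node_ids
    pools: dict[int, list[int]] = {}
    for i, dv in enumerate(deg):
        pools.setdefault(int(dv), []).append(i)
    for pool in pools.values():
        rng.shuffle(pool)
    n_fallback = 0
    order: list[str] = []
    taken = np.zeros(net.n_nodes, dtype=bool)
    for ref in reference_order:
        want = int(deg[net.index_of(ref)])
        d_use = want
        if not pools.get(want):
            nonempty = [d for d, p in pools.items() if p]
            if not nonempty:
                break
            d_use = min(nonempty, key=lambda d: (abs(d - want), d))
            n_fallback += 1
        i = pools[d_use].pop()
        taken[i] = True
        order.append(nodes[i])
    if n_fallback:
        logger.info("degree_matched_schedule: %d position(s) fell back to "
                    "the nearest non-empty degree class", n_fallback)
    rest = np.flatnonzero(~taken)
    rng.shuffle(rest)
    order.extend(nodes[i] for i in rest)
    return RemovalSchedule(order, scheme="degree_matched", seed=seed)
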