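"""Network data model and per-node topology descriptors.

The central object is :class:`Network`, a lightweight immutable simple
undirected graph over string gene identifiers.  Edges are stored as a
canonical ``(E, 2)`` integer index array, which keeps very large graphs
(tens of millions of edges, e.g. a complete graph on ~9000 nodes) within
a desktop memory budget where a dict-of-dicts representation would not.

Gene identifiers are opaque, case-sensitive strings: no symbol
harmonization is attempted, so reading, writing and set operations are
fully deterministic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse import csgraph

logger = logging.getLogger(__name__)

__all__ = [
    "Network",
    "SummaryStats",
    "read_edge_list",
    "write_edge_list",
    "union_networks",
    "network_summary",
    "node_topology",
]


class Network:
    """Simple undirected graph over gene identifiers.

    Invariants enforced at construction: no self-loops, no duplicate
    edges (unordered uniqueness), every edge endpoint is a known node.
    Isolated nodes are allowed.

    Parameters
    ----------
    nodes : sequence of str
        Node identifiers; order defines the internal index.
    edges_idx : (E, 2) integer array, optional
        Edges as index pairs into ``nodes``.  Deduplicated and
        canonicalized unless ``trusted=True``.
    name : str
        Free-form label.
    trusted : bool
        Skip dedup/self-loop filtering for edges known to be canonical
        already (used by generators of very large graphs).
    """

    def __init__(self, nodes: Sequence[str], edges_idx=None, name: str = "",
                 trusted: bool = False):
        self._nodes = list(nodes)
        if len(set(self._nodes)) != len(self._nodes):
            raise ValueError("duplicate node identifiers")
        self._index = {v: i for i, v in enumerate(self._nodes)}
        n = len(self._nodes)
        if edges_idx is None:
            edges_idx = np.empty((0, 2), dtype=np.int64)
        e = np.asarray(edges_idx)
        if e.size and not trusted:
            if e.min() < 0 or e.max() >= n:
                raise ValueError("edge endpoint index out of range")
            lo = np.minimum(e[:, 0], e[:, 1])
            hi = np.maximum(e[:, 0], e[:, 1])
            keep = lo != hi  # drop self-loops
            e = np.unique(np.column_stack([lo[keep], hi[keep]]), axis=0)
        self._edges = np.ascontiguousarray(e, dtype=np.int64).reshape(-1, 2)
        self.name = name
        self._csr_cache = None

    # -- constructors -------------------------------------------------
    @classmethod
    def from_edges(cls, pairs: Iterable[tuple[str, str]],
                   extra_nodes: Iterable[str] = (), name: str = "") -> "Network":
        """Build from an iterable of id pairs; self-loops are dropped."""
        pairs = list(pairs)
        nodes: dict[str, None] = {}
        for u, v in pairs:
            nodes.setdefault(str(u))
            nodes.setdefault(str(v))
        for v in extra_nodes:
            nodes.setdefault(str(v))
        node_list = list(nodes)
        index = {v: i for i, v in enumerate(node_list)}
        if pairs:
            e = np.array([[index[str(u)], index[str(v)]] for u, v in pairs],
                         dtype=np.int64)
        else:
            e = None
        return cls(node_list, e, name=name)

    @classmethod
    def from_networkx(cls, g, name: str = "") -> "Network":
        nodes = [str(v) for v in g.nodes()]
        index = {v: i for i, v in enumerate(g.nodes())}
        if g.number_of_edges():
            e = np.array([[index[u], index[v]] for u, v in g.edges()],
                         dtype=np.int64)
        else:
            e = None
        return cls(nodes, e, name=name or str(g.name))

    @classmethod
    def complete(cls, n: int, name: str = "complete",
                 max_edges: int = 200_000_000) -> "Network":
        """Complete graph on ``n`` nodes (all n(n-1)/2 edges).

        Raises a MemoryError with a hint to halve ``n`` when the edge
        count exceeds ``max_edges``.
        """
        if n < 2:
            raise ValueError("complete graph needs n >= 2")
        n_edges = n * (n - 1) // 2
        if n_edges > max_edges:
            raise MemoryError(
                f"complete graph on {n} nodes has {n_edges} edges, above the "
                f"budget of {max_edges}; consider halving n (n -> n//2)")
        lo, hi = np.triu_indices(n, k=1)
        e = np.column_stack([lo.astype(np.int64), hi.astype(np.int64)])
        nodes = [f"v{i}" for i in range(n)]
        return cls(nodes, e, name=name, trusted=True)

    # -- basic accessors ----------------------------------------------
    @property
    def node_ids(self) -> list[str]:
        return list(self._nodes)

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return self._edges.shape[0]

    @property
    def edges_idx(self) -> np.ndarray:
        return self._edges

    def index_of(self, node: str) -> int:
        return self._index[node]

    def indices_of(self, nodes: Iterable[str]) -> np.ndarray:
        return np.fromiter((self._index[v] for v in nodes), dtype=np.int64)

    def __contains__(self, node: str) -> bool:
        return node in self._index

    def edge_set(self) -> set[tuple[str, str]]:
        """Edges as a set of lexicographically sorted id pairs."""
        out = set()
        for i, j in self._edges:
            u, v = self._nodes[i], self._nodes[j]
            out.add((u, v) if u <= v else (v, u))
        return out

    def degrees(self) -> np.ndarray:
        """Degree per node (internal index order)."""
        return np.bincount(self._edges.ravel(), minlength=self.n_nodes)

    def adjacency_csr(self) -> tuple[np.ndarray, np.ndarray]:
        """Symmetric adjacency in CSR form ``(indptr, indices)``; cached."""
        if self._csr_cache is None:
            n = self.n_nodes
            e = self._edges
            deg = np.bincount(e.ravel(), minlength=n)
            indptr = np.zeros(n + 1, dtype=np.int64)
            np.cumsum(deg, out=indptr[1:])
            src = np.concatenate([e[:, 0], e[:, 1]])
            dst = np.concatenate([e[:, 1], e[:, 0]])
            order = np.argsort(src, kind="stable")
            self._csr_cache = (indptr, np.ascontiguousarray(dst[order]))
        return self._csr_cache

    def to_networkx(self):
        import networkx as nx
        g = nx.Graph(name=self.name)
        g.add_nodes_from(self._nodes)
        g.add_edges_from((self._nodes[i], self._nodes[j]) for i, j in self._edges)
        return g

    def to_sparse(self) -> sparse.csr_matrix:
        n = self.n_nodes
        e = self._edges
        data = np.ones(2 * e.shape[0], dtype=np.int8)
        rows = np.concatenate([e[:, 0], e[:, 1]])
        cols = np.concatenate([e[:, 1], e[:, 0]])
        return sparse.csr_matrix((data, (rows, cols)), shape=(n, n))

    def __repr__(self) -> str:
        label = f" {self.name!r}" if self.name else ""
        return f"<Network{label}: {self.n_nodes} nodes, {self.n_edges} edges>"


@dataclass(frozen=True)
class SummaryStats:
    """Whole-network summary: N, E, mean degree 2E/N, density, components."""
    n_nodes: int
    n_edges: int
    avg_degree: float
    density: float
    n_components: int

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "avg_degree": self.avg_degree,
            "density": self.density,
            "n_components": self.n_components,
        }


class EdgeListParseError(ValueError):
    pass


def read_edge_list(path, has_header: bool = False, name: str = "") -> Network:
    """Read a 2+ column whitespace/tab separated edge list.

    ``#`` lines are comments.  Duplicate lines and reversed duplicates
    collapse to a single edge; self-loop lines are dropped (count
    logged).  Malformed lines raise an error naming the line number.
    """
    pairs: list[tuple[str, str]] = []
    n_self = 0
    with open(path) as fh:
        first_data = True
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if first_data and has_header:
                first_data = False
                continue
            first_data = False
            parts = line.split()
            if len(parts) < 2:
                raise EdgeListParseError(
                    f"{path}: line {lineno}: expected >=2 columns, got {len(parts)}")
            u, v = parts[0], parts[1]
            if u == v:
                n_self += 1
                continue
            pairs.append((u, v))
    if n_self:
        logger.info("read_edge_list: dropped %d self-loop line(s)", n_self)
    if not pairs:
        warnings.warn(f"{path}: no edges read; returning an empty network",
                      stacklevel=2)
    return Network.from_edges(pairs, name=name or str(path))


def write_edge_list(net: Network, path) -> None:
    """Canonical writer: endpoints sorted within each edge, edges sorted."""
    edges = sorted(net.edge_set())
    isolated = sorted(set(net.node_ids)
                      - {u for e in edges for u in e})
    with open(path, "w") as fh:
        for u, v in edges:
            fh.write(f"{u}\t{v}\n")
        if isolated:
            fh.write("# isolated nodes: " + " ".join(isolated) + "\n")


def union_networks(networks: Sequence[Network], name: str = "union") -> Network:
    """Graph union: union of node sets and of deduplicated edge sets."""
    if not networks:
        raise ValueError("union of an empty list of networks")
    nodes: dict[str, None] = {}
    edges: set[tuple[str, str]] = set()
    for net in networks:
        for v in net.node_ids:
            nodes.setdefault(v)
        edges |= net.edge_set()
    return Network.from_edges(sorted(edges), extra_nodes=nodes, name=name)


def network_summary(net: Network) -> SummaryStats:
    """N, E, average degree 2E/N, density 2E/(N(N-1)), component count."""
    n, e = net.n_nodes, net.n_edges
    if n < 1:
        raise ValueError("summary of an empty network")
    avg = 2.0 * e / n
    density = 2.0 * e / (n * (n - 1)) if n >= 2 else 0.0
    n_comp, _ = csgraph.connected_components(net.to_sparse(), directed=False)
    return SummaryStats(n, e, avg, density, int(n_comp))


def node_topology(net: Network) -> pd.DataFrame:
    """Per-node degree, local clustering coefficient and mean neighbor degree.

    Clustering is 0 for degree < 2; mean neighbor degree is NaN for
    isolated nodes.  Scores always refer to the intact input network.
    """
    import networkx as nx
    g = net.to_networkx()
    deg = dict(g.degree())
    cc = nx.clustering(g)
    nbr = nx.average_neighbor_degree(g)
    rows = []
    for v in net.node_ids:
        rows.append({
            "node": v,
            "degree": deg[v],
            "clustering": cc[v],
            "neighbor_degree": nbr[v] if deg[v] > 0 else np.nan,
        })
    return pd.DataFrame(rows).set_index("node")
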