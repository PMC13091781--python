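"""Fragmentation-entropy resilience of networks under node failure.

A node *failure* (or isolation) deletes every edge incident to the node
but keeps the node as a size-1 component, so the total node count N is
constant along a removal trajectory.  Fragmentation after isolating a
fraction ``f`` of nodes is quantified by the normalized Shannon
diversity of component sizes,

    S(f) = -(1 / ln N) * sum_i p_i ln p_i,      p_i = n_i / N,

which is 0 for a single connected component and 1 when every node is
isolated.  Overall resilience is

    R = 1 - integral_0^1 S(f) df,

evaluated by the composite trapezoid rule on the recorded grid (one
point per removal step, endpoints f=0 and f=1 always present).  Higher
R means the network fragments later/less.

Failure schemes: ``random`` (uniform order), ``degree`` / ``clustering``
(non-increasing intact-network score, ties permuted uniformly at
random), ``custom`` (caller-supplied score), plus mutation-frequency
orders built in :mod:`panresil.mutations`.  ``degree`` is static (the
score is never recomputed); ``degree_adaptive`` recomputes degrees
after every isolation, the classical adaptive hub attack that the
benchmark tables of this kind report for "targeted" removal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from ._kernel import entropy_curve
from .network import Network

__all__ = [
    "RemovalSchedule",
    "FragmentationCurve",
    "ResilienceEstimate",
    "ComparisonResult",
    "shannon_diversity",
    "build_schedule",
    "fragmentation_curve",
    "integrate_resilience",
    "ideal_max_resilience",
    "neighborhood_fragmentation_curve",
    "estimate_resilience",
    "compare_estimates",
    "child_seed",
]

SCHEMES = ("random", "degree", "degree_adaptive", "clustering",
           "mutation_frequency", "custom")


def child_seed(master: int, *key: int) -> np.random.Generator:
    """Deterministic child RNG from a master seed and an integer path.

    The spawn-key scheme makes every replicate reproducible from the
    single master seed independently of evaluation order.
    """
    return np.random.default_rng(np.random.SeedSequence(master, spawn_key=key))


@dataclass
class RemovalSchedule:
    """Ordered node list driving a fragmentation curve."""
    order: list[str]
    scheme: str
    seed: int | None = None

    def __post_init__(self):
        if len(set(self.order)) != len(self.order):
            raise ValueError("schedule contains duplicate nodes")


@dataclass
class FragmentationCurve:
    """Paired (f, S) samples along a removal trajectory."""
    f: np.ndarray
    S: np.ndarray
    N: int
    scheme: str = ""

    def __post_init__(self):
        self.f = np.asarray(self.f, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        if self.f.shape != self.S.shape:
            raise ValueError("f and S must have equal length")

    @property
    def R(self) -> float:
        return integrate_resilience(self)


@dataclass
class ResilienceEstimate:
    """Replicate statistics of R for one network/scheme combination."""
    mean_R: float
    sem: float
    n_reps: int
    per_rep_R: list[float]
    scheme: str
    network_label: str = ""

    def summary(self) -> str:
        return (f"{self.network_label or 'network'} [{self.scheme}]: "
                f"R = {self.mean_R:.6f} (sem {self.sem:.2e}, "
                f"n = {self.n_reps})")


@dataclass
class ComparisonResult:
    """Welch two-sample t comparison of two resilience estimates."""
    difference: float
    t_statistic: float
    p_value: float
    ci95: tuple[float, float]


def shannon_diversity(component_sizes: Sequence[int], N: int) -> float:
    """Normalized Shannon diversity of component sizes (base-free).

    Requires N >= 2 and sizes summing exactly to N.
    """
    sizes = np.asarray(component_sizes, dtype=np.int64)
    if N < 2:
        raise ValueError("normalization undefined for N < 2")
    if sizes.size == 0 or (sizes < 1).any():
        raise ValueError("component sizes must be >= 1")
    if sizes.sum() != N:
        raise ValueError(f"component sizes sum to {sizes.sum()}, expected {N}")
    p = sizes / N
    return float(-(p * np.log(p)).sum() / math.log(N))


def _scores_for_scheme(net: Network, scheme: str,
                       aux: Mapping[str, float] | None) -> np.ndarray:
    if scheme == "degree":
        return net.degrees().astype(float)
    if scheme == "clustering":
        from .network import node_topology
        topo = node_topology(net)
        return topo.loc[net.node_ids, "clustering"].to_numpy(dtype=float)
    if scheme == "custom":
        if aux is None:
            raise ValueError("custom scheme requires per-node scores (aux)")
        return np.array([aux[v] for v in net.node_ids], dtype=float)
    raise ValueError(f"unknown scheme {scheme!r}")


def _adaptive_degree_order(net: Network,
                           rng: np.random.Generator) -> np.ndarray:
    """Node order of the adaptive hub attack.

    Repeatedly isolates a node of currently maximal degree, recomputing
    degrees after every isolation; ties are broken uniformly at random.
    Lazy-deletion heap, O((N + E) log N).
    """
    import heapq

    n = net.n_nodes
    indptr, indices = net.adjacency_csr()
    deg = net.degrees().astype(np.int64).copy()
    tie = rng.random(n)
    heap = [(-deg[i], tie[i], i) for i in range(n)]
    heapq.heapify(heap)
    removed = np.zeros(n, dtype=bool)
    order = np.empty(n, dtype=np.int64)
    pos = 0
    while heap:
        negd, t, v = heapq.heappop(heap)
        if removed[v]:
            continue
        if -negd != deg[v]:  # stale entry: reinsert at current degree
            heapq.heappush(heap, (-int(deg[v]), t, v))
            continue
        removed[v] = True
        order[pos] = v
        pos += 1
        for k in range(indptr[v], indptr[v + 1]):
            u = indices[k]
            if not removed[u]:
                deg[u] -= 1
    return order


def build_schedule(net: Network, scheme: str, seed: int,
                   aux: Mapping[str, float] | None = None) -> RemovalSchedule:
    """Full-network removal order for a failure scheme.

    random: uniform permutation.  degree/clustering/custom: nodes in
    non-increasing intact-network score, ties permuted uniformly at
    random.
    """
    rng = np.random.default_rng(seed)
    n = net.n_nodes
    if scheme == "random":
        perm = rng.permutation(n)
    elif scheme == "degree_adaptive":
        perm = _adaptive_degree_order(net, rng)
    else:
        scores = _scores_for_scheme(net, scheme, aux)
        # sort by descending score, random key inside ties
        perm = np.lexsort((rng.random(n), -scores))
    nodes = net.node_ids
    return RemovalSchedule([nodes[i] for i in perm], scheme=scheme, seed=seed)


def fragmentation_curve(net: Network,
                        schedule: RemovalSchedule) -> FragmentationCurve:
    """S(f) at f = k/N for k = 0..N along the schedule.

    Step k isolates schedule node k (its remaining edges are deleted;
    the node stays as a size-1 component).  Computed by processing the
    order in reverse with incremental component merging, so one curve
    costs O((N+E) alpha(N)).
    """
    n = net.n_nodes
    if len(schedule.order) != n:
        raise ValueError("schedule must cover every network node exactly once")
    order = net.indices_of(schedule.order)
    indptr, indices = net.adjacency_csr()
    s_vals = entropy_curve(indptr, indices, order, n)
    f = np.arange(n + 1) / n
    return FragmentationCurve(f, s_vals, N=n, scheme=schedule.scheme)


def integrate_resilience(curve: FragmentationCurve) -> float:
    """R = 1 - trapezoidal integral of S over f; lies in [0, 1]."""
    return float(1.0 - np.trapezoid(curve.S, curve.f))


def ideal_max_resilience(N: int) -> float:
    """Maximum attainable R at size N (fully connected limit).

    On a complete graph the curve after k isolations is exactly
    ``S(k/N) = k/N + ((N-k)/N) * ln(N/(N-k)) / ln N``; this evaluates
    that curve on the discrete grid and integrates it with the same
    trapezoid rule used everywhere else.  The continuum closed form is
    ``1/2 - 1/(4 ln N)`` (-> 1/2 as N -> infinity).
    """
    if N < 2:
        raise ValueError("N >= 2 required")
    k = np.arange(N + 1)
    rem = N - k
    s = k / N
    mask = rem > 0
    s = s + np.where(mask, (rem / N) * np.log(np.where(mask, N / np.maximum(rem, 1), 1.0)) / math.log(N), 0.0)
    s[-1] = 1.0
    return float(1.0 - np.trapezoid(s, k / N))


def neighborhood_fragmentation_curve(net: Network, scheme: str, seed: int,
                                     aux: Mapping[str, float] | None = None,
                                     order: Sequence[str] | None = None,
                                     ) -> FragmentationCurve:
    """Curve when each step isolates a node *and* its remaining neighbors.

    The next not-yet-isolated node by the scheme's priority is selected;
    it and all of its currently remaining neighbors are isolated in one
    step, and (f, S) is recorded after each step.  The f spacing is
    irregular; the trapezoid rule still applies for R.
    """
    n = net.n_nodes
    if order is not None:
        priority = net.indices_of(order)
        if priority.shape[0] != n:
            raise ValueError("explicit order must cover all nodes")
    else:
        priority = net.indices_of(
            build_schedule(net, scheme, seed, aux=aux).order)
    indptr, indices = net.adjacency_csr()
    removed = np.zeros(n, dtype=bool)
    flat = np.empty(n, dtype=np.int64)
    boundaries = [0]
    pos = 0
    for v in priority:
        if removed[v]:
            continue
        group = [v]
        removed[v] = True
        for k in range(indptr[v], indptr[v + 1]):
            u = indices[k]
            if not removed[u]:
                removed[u] = True
                group.append(u)
        flat[pos:pos + len(group)] = group
        pos += len(group)
        boundaries.append(pos)
    assert pos == n
    s_full = entropy_curve(indptr, indices, flat, n)
    b = np.asarray(boundaries)
    return FragmentationCurve(b / n, s_full[b], N=n,
                              scheme=f"{scheme}+neighbors")


def _as_network(net_source, seed_rng: np.random.Generator) -> Network:
    from .nulls import NullConfig, build_null
    if isinstance(net_source, Network):
        return net_source
    if isinstance(net_source, NullConfig):
        return build_null(net_source,
                          seed=int(seed_rng.integers(2**31)))
    raise TypeError(f"cannot interpret {type(net_source)!r} as a network source")


def estimate_resilience(net_source, scheme: str = "random",
                        n_networks: int = 1, n_reps: int = 100,
                        seed: int = 0,
                        aux: Mapping[str, float] | None = None,
                        neighborhood: bool = False,
                        label: str = "") -> ResilienceEstimate:
    """Replicate mean and s.e.m. of R over networks x schedule seeds.

    For a generated model (``NullConfig``) ``n_networks`` instances are
    drawn; for a fixed :class:`Network` the network is reused and only
    schedule seeds vary.  Bit-reproducible from ``seed`` via the spawn
    scheme in :func:`child_seed`.
    """
    from .nulls import NullConfig
    if n_networks < 1 or n_reps < 1:
        raise ValueError("n_networks and n_reps must be >= 1")
    per_rep: list[float] = []
    fixed = isinstance(net_source, Network)
    n_nets = 1 if fixed else n_networks
    for i in range(n_nets):
        net = _as_network(net_source, child_seed(seed, 0, i))
        for j in range(n_reps):
            rep_rng = child_seed(seed, 1, i, j)
            rep_seed = int(rep_rng.integers(2**31))
            if neighborhood:
                curve = neighborhood_fragmentation_curve(
                    net, scheme, rep_seed, aux=aux)
            else:
                sched = build_schedule(net, scheme, rep_seed, aux=aux)
                curve = fragmentation_curve(net, sched)
            per_rep.append(curve.R)
    arr = np.asarray(per_rep)
    sem = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else 0.0
    if not label:
        label = net_source.name if fixed else getattr(net_source, "model", "")
    return ResilienceEstimate(float(arr.mean()), sem, arr.size,
                              per_rep, scheme, network_label=label)


def compare_estimates(a: ResilienceEstimate,
                      b: ResilienceEstimate) -> ComparisonResult:
    """Welch two-sample t test on per-replicate R values (two-sided)."""
    xa, xb = np.asarray(a.per_rep_R), np.asarray(b.per_rep_R)
    if xa.size < 2 or xb.size < 2:
        raise ValueError("need >= 2 replicates on each side")
    diff = float(xa.mean() - xb.mean())
    if xa.std() == 0.0 and xb.std() == 0.0:
        # both deterministic: identical means -> no evidence of difference
        if diff == 0.0:
            return ComparisonResult(0.0, 0.0, 1.0, (0.0, 0.0))
        return ComparisonResult(diff, math.copysign(math.inf, diff), 0.0,
                                (diff, diff))
    res = stats.ttest_ind(xa, xb, equal_var=False)
    ci = res.confidence_interval(0.95)
    return ComparisonResult(float(xa.mean() - xb.mean()),
                            float(res.statistic), float(res.pvalue),
                            (float(ci.low), float(ci.high)))
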