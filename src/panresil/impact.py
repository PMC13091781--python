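"""Per-gene leave-one-out impact on resilience and derived analyses.

The leave-one-out (LOO) scan fixes one mutation-frequency removal
schedule and, for each mutated gene in turn, treats that gene as
non-mutated: it is pulled out of the frequency-ordered prefix and
re-inserted at a seeded random position of the random background
suffix, leaving the ordering of every other gene untouched.  The
resilience recomputed under this modified schedule, R_loo, measures the
gene's incremental contribution to fragmentation *including* the
cumulative (memory) effect of genes removed before it: the higher
R_loo, the more that gene's mutation costs the network.

The bimodal R_loo distribution is split into high/low-impact groups by
a peak-symmetry cutoff: a Gaussian KDE locates the main (highest) peak,
its left flank at a small fraction of the peak height is reflected to
the right of the mode, and everything beyond that reflection is called
high impact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .mutations import MutationCounts, mutation_order_schedule
from .network import Network
from .resilience import (RemovalSchedule, child_seed, fragmentation_curve)

__all__ = [
    "ImpactGroups",
    "MemoryCurve",
    "CCTestResult",
    "OverlapResult",
    "loo_impact_scan",
    "impact_groups",
    "impact_ranking",
    "memory_effect_curve",
    "mutated_cc_test",
    "catalog_overlap",
]


@dataclass
class ImpactGroups:
    cutoff: float
    high_impact: set[str]
    low_impact: set[str]
    kde_bandwidth: float
    main_peak_mode: float


@dataclass
class MemoryCurve:
    prefix_sizes: np.ndarray
    delta: np.ndarray      # mean R_m - R_r per prefix
    sem: np.ndarray
    group_size: int


@dataclass
class CCTestResult:
    u_statistic: float
    p_value: float
    median_mutated: float
    median_other: float


@dataclass
class OverlapResult:
    n_query: int
    n_catalog: int
    n_overlap: int
    overlap_genes: set[str]


def _loo_order(prefix: list[str], suffix: list[str], gene: str,
               insert_at: int) -> list[str]:
    """Order with ``gene`` moved from the prefix into the suffix."""
    new_prefix = [g for g in prefix if g != gene]
    new_suffix = list(suffix)
    new_suffix.insert(insert_at, gene)
    return new_prefix + new_suffix


def loo_impact_scan(net: Network, counts: MutationCounts, seed: int = 0,
                    control_mode: str = "mutation",
                    genes: list[str] | None = None) -> pd.DataFrame:
    """Leave-one-out resilience per scored gene.

    Returns a DataFrame indexed by gene with columns ``degree``,
    ``mutated_samples`` and ``R_loo``; the shared baseline resilience
    and control mode are stored in ``df.attrs``.  ``control_mode``
    "mutation" scores the mutated genes against the mutation-frequency
    baseline; "degree" is the supplementary control in which the scored
    list is the same number of genes taken by decreasing degree.
    Per-gene insertion positions are derived from ``seed`` by gene rank,
    so results do not depend on the subset or order of ``genes``.
    """
    if control_mode not in ("mutation", "degree"):
        raise ValueError("control_mode must be 'mutation' or 'degree'")
    base_seed = int(child_seed(seed, 10).integers(2**31))
    if control_mode == "mutation":
        base = mutation_order_schedule(counts, seed=base_seed)
        n_prefix = len(counts.mutated_genes())
    else:
        from .resilience import build_schedule
        full = build_schedule(net, "degree", base_seed)
        n_prefix = len(counts.mutated_genes())
        base = RemovalSchedule(full.order, scheme="degree_control",
                               seed=base_seed)
    prefix = base.order[:n_prefix]
    suffix = base.order[n_prefix:]
    baseline_R = fragmentation_curve(net, base).R

    deg = dict(zip(net.node_ids, net.degrees()))
    cnt = counts.counts
    rank = {g: i for i, g in enumerate(prefix)}
    if genes is None:
        scored = list(prefix)
    else:
        scored = []
        for g in genes:
            if g in rank:
                scored.append(g)
            else:
                import warnings
                warnings.warn(f"gene {g!r} is not in the scored prefix "
                              "(count 0 or absent); skipped", stacklevel=2)
    rows = []
    for g in scored:
        rng_g = child_seed(seed, 20, rank[g])
        insert_at = int(rng_g.integers(len(suffix) + 1))
        order = _loo_order(prefix, suffix, g, insert_at)
        r_loo = fragmentation_curve(
            net, RemovalSchedule(order, scheme="loo", seed=seed)).R
        rows.append({"gene": g, "degree": int(deg[g]),
                     "mutated_samples": int(cnt.get(g, 0)), "R_loo": r_loo})
    df = pd.DataFrame(rows).set_index("gene").sort_values(
        "R_loo", ascending=False)
    df.attrs["baseline_R_m"] = baseline_R
    df.attrs["control_mode"] = control_mode
    df.attrs["seed"] = seed
    return df


def impact_groups(table: pd.DataFrame, alpha_height: float = 0.05,
                  bw_method="silverman", min_genes: int = 100,
                  grid_size: int = 2048) -> ImpactGroups:
    """Split R_loo values into high/low impact by peak symmetry.

    A Gaussian KDE (Silverman bandwidth by default) is evaluated on a
    grid; mu is the mode of the highest peak, l the smallest value
    whose density reaches ``alpha_height`` of the peak height, and the
    cutoff is mu + (mu - l) — the left flank reflected to the right.
    Genes with R_loo above the cutoff form the high-impact group (which
    may legitimately be empty for a narrow unimodal distribution).
    """
    x = table["R_loo"].to_numpy(dtype=float)
    if x.size < min_genes:
        raise ValueError(f"need >= {min_genes} scored genes for a "
                         "meaningful density estimate")
    kde = stats.gaussian_kde(x, bw_method=bw_method)
    bw = float(kde.factor * x.std(ddof=1))
    pad = 4 * bw
    grid = np.linspace(x.min() - pad, x.max() + pad, grid_size)
    dens = kde(grid)
    peak = int(np.argmax(dens))
    # peak position as the density-weighted center of the half-height
    # region around the argmax: far less wobble than the raw argmax
    half = 0.5 * dens[peak]
    lo = peak
    while lo > 0 and dens[lo - 1] >= half:
        lo -= 1
    hi = peak
    while hi < grid_size - 1 and dens[hi + 1] >= half:
        hi += 1
    w = dens[lo:hi + 1]
    mu = float((grid[lo:hi + 1] * w).sum() / w.sum())
    thresh = alpha_height * dens[peak]
    above = np.flatnonzero(dens >= thresh)
    left = float(grid[above[0]])
    cutoff = mu + (mu - left)
    high = set(table.index[x > cutoff])
    low = set(table.index) - high
    return ImpactGroups(cutoff=cutoff, high_impact=high, low_impact=low,
                        kde_bandwidth=bw, main_peak_mode=mu)


def impact_ranking(table: pd.DataFrame, topo: pd.DataFrame | None = None,
                   k: int = 10) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-k genes by degree and by R_loo (ties broken lexicographically).

    Both tables carry (gene, degree, mutated_samples, R_loo) rows, the
    shape of a side-by-side hubs-vs-impact comparison.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    df = table.reset_index()
    if topo is not None:
        deg = topo["degree"]
        df["degree"] = df["gene"].map(deg).fillna(df["degree"]).astype(int)
    by_degree = df.sort_values(["degree", "gene"],
                               ascending=[False, True]).head(k)
    by_impact = df.sort_values(["R_loo", "gene"],
                               ascending=[False, True]).head(k)
    cols = ["gene", "degree", "mutated_samples", "R_loo"]
    return (by_degree[cols].reset_index(drop=True),
            by_impact[cols].reset_index(drop=True))


def memory_effect_curve(net: Network, counts: MutationCounts,
                        group_size: int = 5, n_reps: int = 20,
                        seed: int = 0,
                        prefix_sizes=None) -> MemoryCurve:
    """Cumulative (memory) effect of the most frequently mutated genes.

    For each prefix size 5k (multiples of ``group_size``) the top-5k
    genes by mutation frequency are removed first, in frequency order,
    and the rest of the network uniformly at random; delta(k) is the
    mean over replicates of R_m(k) - R_r against a fully random
    baseline sharing the same replicate seeds.
    """
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    genes = np.asarray(counts.counts.index)
    vals = counts.counts.to_numpy()
    node_set = np.asarray(net.node_ids)
    n = net.n_nodes
    n_mut = int((vals > 0).sum())
    if prefix_sizes is None:
        prefix_sizes = list(range(0, n_mut + group_size, group_size))
        prefix_sizes[-1] = min(prefix_sizes[-1], n_mut)
        prefix_sizes = sorted(set(prefix_sizes))
    prefix_sizes = np.asarray(prefix_sizes, dtype=int)
    deltas = np.empty((len(prefix_sizes), n_reps))
    for r in range(n_reps):
        rng = child_seed(seed, 30, r)
        # frequency order with per-replicate tie permutation
        order_mut = np.lexsort((rng.random(len(genes)), -vals))
        order_mut = order_mut[vals[order_mut] > 0]
        base_perm = rng.permutation(n)
        r_rand = fragmentation_curve(net, RemovalSchedule(
            [node_set[i] for i in base_perm], scheme="random")).R
        for pi, p in enumerate(prefix_sizes):
            head = [str(genes[i]) for i in order_mut[:p]]
            head_set = set(head)
            tail_perm = rng.permutation(n)
            tail = [node_set[i] for i in tail_perm
                    if node_set[i] not in head_set]
            r_m = fragmentation_curve(net, RemovalSchedule(
                head + tail, scheme="mutation_frequency")).R
            deltas[pi, r] = r_m - r_rand
    mean = deltas.mean(axis=1)
    sem = (deltas.std(axis=1, ddof=1) / math.sqrt(n_reps)
           if n_reps > 1 else np.zeros(len(prefix_sizes)))
    return MemoryCurve(prefix_sizes, mean, sem, group_size)


def mutated_cc_test(topo: pd.DataFrame, mutated: set[str]) -> CCTestResult:
    """Rank-sum comparison of clustering coefficients, mutated vs rest.

    Two-sided Wilcoxon-Mann-Whitney test on the local clustering
    coefficients of mutated genes against all other network genes.
    """
    is_mut = topo.index.isin(mutated)
    cc_mut = topo.loc[is_mut, "clustering"].to_numpy()
    cc_other = topo.loc[~is_mut, "clustering"].to_numpy()
    if cc_mut.size == 0 or cc_other.size == 0:
        raise ValueError("both groups must be non-empty")
    u, p = stats.mannwhitneyu(cc_mut, cc_other, alternative="two-sided")
    return CCTestResult(float(u), float(p),
                        float(np.median(cc_mut)), float(np.median(cc_other)))


def catalog_overlap(query: set[str], catalog: set[str]) -> OverlapResult:
    """Exact string intersection of a gene list with a catalog."""
    query, catalog = set(query), set(catalog)
    inter = query & catalog
    return OverlapResult(len(query), len(catalog), len(inter), inter)
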