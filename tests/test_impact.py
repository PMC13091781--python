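import itertools
import math

import numpy as np
import pandas as pd
import pytest

from panresil.impact import (catalog_overlap, impact_groups, impact_ranking,
                             loo_impact_scan, memory_effect_curve,
                             mutated_cc_test)
from panresil.mutations import MutationCounts
from panresil.network import Network, node_topology


def make_counts(mapping, net):
    s = pd.Series(mapping).reindex(net.node_ids, fill_value=0).astype(int)
    return MutationCounts(s, n_samples=max(list(mapping.values()) + [1]),
                          restricted_to_network=True)


# -- leave-one-out scan --------------------------------------------------


def test_loo_noop_exclusion_of_last_gene():
    # every gene mutated, g uniquely last (lowest count): the suffix is
    # empty, so moving g there reproduces the baseline order exactly
    net = Network.from_edges([("a", "b"), ("b", "c"), ("c", "d")])
    counts = make_counts({"a": 9, "b": 5, "c": 3, "d": 1}, net)
    table = loo_impact_scan(net, counts, seed=0)
    assert table.loc["d", "R_loo"] == pytest.approx(
        table.attrs["baseline_R_m"], abs=1e-15)


def test_loo_bridge_gene_tops_barbell():
    # two 8-cliques joined through one low-frequency bridge node: moving
    # the bridge out of the mutated prefix delays the split the longest,
    # so brute force over all exclusions ranks it first
    edges = []
    for side in ("L", "R"):
        names = [f"{side}{i}" for i in range(8)]
        edges += list(itertools.combinations(names, 2))
    # the bridge anchors to half of each clique so it keeps the halves
    # joined until deep into the removal trajectory
    edges += [(f"L{i}", "X") for i in range(4)]
    edges += [("X", f"R{i}") for i in range(4)]
    net = Network.from_edges(edges)
    # only a handful of genes are mutated: the bridge sits at the bottom
    # of the frequency order, everything else stays in the random suffix
    mapping = {"L0": 10, "L1": 9, "R0": 8, "R1": 7, "X": 1}
    counts = make_counts(mapping, net)
    for seed in (1, 2, 3):
        table = loo_impact_scan(net, counts, seed=seed)
        assert table["R_loo"].idxmax() == "X"


def test_loo_skips_unscored_gene_with_warning():
    net = Network.from_edges([("a", "b"), ("b", "c")])
    counts = make_counts({"a": 2, "b": 1}, net)
    with pytest.warns(UserWarning, match="skipped"):
        table = loo_impact_scan(net, counts, seed=0, genes=["a", "c"])
    assert list(table.index) == ["a"]


def test_loo_independent_of_scored_subset():
    net = Network.from_edges([(f"g{i}", f"g{(i + 1) % 12}")
                              for i in range(12)])
    counts = make_counts({f"g{i}": 10 - i for i in range(10)}, net)
    full = loo_impact_scan(net, counts, seed=7)
    sub = loo_impact_scan(net, counts, seed=7, genes=["g3", "g5"])
    for g in ("g3", "g5"):
        assert sub.loc[g, "R_loo"] == full.loc[g, "R_loo"]


# -- impact groups (peak-symmetry cutoff) --------------------------------


def _table_from_values(values):
    return pd.DataFrame({
        "gene": [f"g{i}" for i in range(len(values))],
        "degree": 1, "mutated_samples": 1, "R_loo": values,
    }).set_index("gene")


def test_groups_symmetric_normal_nearly_empty_high_set():
    rng = np.random.default_rng(0)
    table = _table_from_values(rng.normal(0.45, 1e-4, 5000))
    grp = impact_groups(table)
    assert len(grp.high_impact) <= 0.01 * len(table)


def test_groups_recover_planted_mixture():
    # 95% main peak at 0.452, 5% high-impact mode at 0.4535
    rng = np.random.default_rng(1)
    n = 10_000
    labels = rng.random(n) < 0.05
    x = np.where(labels, rng.normal(0.4535, 1e-4, n),
                 rng.normal(0.452, 1e-4, n))
    grp = impact_groups(_table_from_values(x))
    truth = {f"g{i}" for i in np.flatnonzero(labels)}
    assert abs(len(grp.high_impact) - 500) <= 0.15 * 500
    recall = len(grp.high_impact & truth) / len(truth)
    assert recall >= 0.95


def test_groups_partition_and_cutoff_rule():
    rng = np.random.default_rng(2)
    table = _table_from_values(rng.normal(0.3, 0.01, 500))
    grp = impact_groups(table)
    assert grp.high_impact | grp.low_impact == set(table.index)
    assert grp.high_impact == {
        g for g in table.index if table.loc[g, "R_loo"] > grp.cutoff}


def test_groups_need_enough_genes():
    with pytest.raises(ValueError):
        impact_groups(_table_from_values(np.linspace(0, 1, 50)))


# -- rankings ------------------------------------------------------------


def test_ranking_hand_sorted():
    table = pd.DataFrame({
        "gene": ["a", "b", "c"], "degree": [5, 9, 2],
        "mutated_samples": [1, 2, 3], "R_loo": [0.3, 0.1, 0.2],
    }).set_index("gene")
    by_deg, by_imp = impact_ranking(table, k=3)
    assert list(by_deg["gene"]) == ["b", "a", "c"]
    assert list(by_imp["gene"]) == ["a", "c", "b"]


def test_ranking_ties_lexicographic():
    table = pd.DataFrame({
        "gene": ["z", "m", "a"], "degree": [1, 1, 1],
        "mutated_samples": [0, 0, 0], "R_loo": [0.5, 0.5, 0.5],
    }).set_index("gene")
    _, by_imp = impact_ranking(table, k=3)
    assert list(by_imp["gene"]) == ["a", "m", "z"]


# -- memory effect -------------------------------------------------------


def test_memory_prefix_zero_and_full_prefix(synth_default):
    net, truth, counts = synth_default
    n_mut = len(counts.mutated_genes())
    mc = memory_effect_curve(net, counts, group_size=5, n_reps=12, seed=4,
                             prefix_sizes=[0, n_mut])
    assert abs(mc.delta[0]) < 3 * mc.sem[0]          # no prefix, no effect
    # full prefix reproduces the main R_m - R_r contrast: strongly negative
    assert mc.delta[-1] < -5 * mc.sem[-1]


def test_memory_effect_appears_after_planted_ranks(synth_default):
    # bridges land mid-ranking; tiny prefixes exclude them, large include
    net, truth, counts = synth_default
    mc = memory_effect_curve(net, counts, group_size=5, n_reps=10, seed=9,
                             prefix_sizes=[0, 10, 120])
    assert mc.delta[2] < mc.delta[0] - 3 * (mc.sem[0] + mc.sem[2])


# -- clustering-coefficient contrast -------------------------------------


def _topo_from_cc(cc_by_node):
    return pd.DataFrame({
        "node": list(cc_by_node), "degree": 2,
        "clustering": list(cc_by_node.values()),
        "neighbor_degree": 1.0,
    }).set_index("node")


def test_cc_test_identical_distributions():
    cc = {f"m{i}": v for i, v in enumerate(np.linspace(0, 1, 20))}
    cc.update({f"o{i}": v for i, v in enumerate(np.linspace(0, 1, 20))})
    res = mutated_cc_test(_topo_from_cc(cc), {f"m{i}" for i in range(20)})
    assert res.p_value > 0.9


def test_cc_test_strictly_larger_group():
    cc = {f"m{i}": 0.6 + 0.004 * i for i in range(50)}
    cc.update({f"o{i}": 0.1 + 0.004 * i for i in range(50)})
    res = mutated_cc_test(_topo_from_cc(cc), {f"m{i}" for i in range(50)})
    assert res.p_value < 1e-3
    assert res.median_mutated > res.median_other


def test_cc_test_matches_exact_rank_sum_enumeration():
    # tiny two-group case: exact two-sided p by enumerating assignments
    mut_cc = [0.9, 0.7, 0.5]
    oth_cc = [0.6, 0.4, 0.2, 0.1]
    cc = {f"m{i}": v for i, v in enumerate(mut_cc)}
    cc.update({f"o{i}": v for i, v in enumerate(oth_cc)})
    res = mutated_cc_test(_topo_from_cc(cc), set(cc) - {f"o{i}" for i in range(4)})
    pooled = mut_cc + oth_cc
    ranks = {v: r + 1 for r, v in enumerate(sorted(pooled))}

    def u_of(sub):
        rsum = sum(ranks[v] for v in sub)
        return rsum - len(sub) * (len(sub) + 1) / 2

    u_obs = u_of(mut_cc)
    n1, n2 = len(mut_cc), len(oth_cc)
    us = [u_of(sub) for sub in itertools.combinations(pooled, n1)]
    # two-sided: double the smaller tail of the exact U distribution
    ge = sum(u >= u_obs for u in us) / len(us)
    le = sum(u <= u_obs for u in us) / len(us)
    p_exact = min(1.0, 2 * min(ge, le))
    assert res.p_value == pytest.approx(p_exact, abs=1e-10)


def test_cc_test_empty_group_rejected():
    topo = _topo_from_cc({"a": 0.2, "b": 0.4})
    with pytest.raises(ValueError):
        mutated_cc_test(topo, set())


# -- catalog overlap -----------------------------------------------------


def test_catalog_overlap_cases():
    assert catalog_overlap({"a", "b"}, {"c"}).n_overlap == 0
    res = catalog_overlap({"a", "b"}, {"a", "b", "c"})
    assert res.n_overlap == res.n_query == 2
    assert res.overlap_genes == {"a", "b"}
    assert res.n_overlap <= min(res.n_query, res.n_catalog)


# -- degree-control distribution -----------------------------------------


def test_degree_control_unimodal_on_unstructured_network():
    # single ER module, no bridges/hubs: the degree-ordered control must
    # not manufacture a separated high-impact group
    from panresil.mutations import gene_mutation_counts
    from panresil.synth import SynthConfig, synth_mutations, synth_network
    cfg = SynthConfig(n_modules=1, module_size=150, n_bridges=0, n_hubs=0,
                      p_intra=0.05, seed=3)
    net, truth = synth_network(cfg)
    assert truth.planted_high_impact == set()
    counts = gene_mutation_counts(synth_mutations(net, truth, cfg), net)
    table = loo_impact_scan(net, counts, seed=11, control_mode="degree")
    grp = impact_groups(table)
    # a continuous unimodal tail may cross the reflected-flank cutoff,
    # but there must be no *separated* upper mode: the boundary between
    # the groups stays within one KDE bandwidth (no density gap)
    assert len(grp.high_impact) <= 0.15 * len(table)
    if grp.high_impact:
        lo_max = table.loc[list(grp.low_impact), "R_loo"].max()
        hi_min = table.loc[list(grp.high_impact), "R_loo"].min()
        assert hi_min - lo_max < grp.kde_bandwidth
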