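# panresil

Fragmentation-entropy resilience of gene-interaction networks under
random, targeted and mutation-ordered node failure.

`panresil` is for systems biologists who want to ask how much a
protein-protein interaction (PPI) network's integrity depends on
specific genes — in particular, which somatically mutated genes in a
tumor cohort contribute disproportionately to fragmenting the
interactome, beyond what node degree or mutation frequency reveal.

## The measure

A gene failure is modeled as node *isolation*: every edge incident to
the node is deleted, the node remains as a size-1 component, and the
node count N stays constant. After isolating a fraction *f* of nodes,
fragmentation is quantified by the normalized Shannon diversity of
component sizes

    S(f) = -(1 / ln N) * Σ_i p_i ln p_i ,   p_i = n_i / N ,

which is 0 for a single connected component and 1 when every node is
isolated. Overall resilience is

    R = 1 - ∫₀¹ S(f) df ,

evaluated with the composite trapezoid rule on one point per removal
step. Higher R means the network fragments later. A single curve costs
O((N+E)·α(N)) via reverse union-find, so full-interactome trajectories
(N ≈ 17k, E ≈ 600k) take well under a second.

Failure schemes: uniformly `random`; `degree` / `clustering` /
`custom` (static intact-network scores, descending, ties permuted at
random); `degree_adaptive` (the classical hub attack with degrees
recomputed after every isolation); and mutation-frequency order, where
genes are removed by decreasing count of mutated samples, random
within ties, with non-mutated genes following in random order.

On top of the curve engine the package provides: matched null models
(complete, random-regular, Erdős–Rényi, Barabási–Albert),
degree-matched control schedules, leave-one-out per-gene impact scans
with a peak-symmetry cutoff separating high- from low-impact genes,
memory-effect curves, clustering-coefficient rank tests, degree-tail
model comparison (power law vs log-normal), Fisher/Benjamini–Hochberg
over-representation analysis, and a synthetic-data generator with
planted high-impact bridge genes for end-to-end testing.

## Worked example

Everything below runs offline on generated data:

```
panresil synth --seed 2 --out-prefix sim/
panresil stats sim/edges.tsv --out sim/summary.json
panresil impact sim/edges.tsv sim/mutations.tsv --seed 7 \
    --out sim/impact.tsv --groups-out sim/groups.json
```

The first command writes a modular, disassortative 494-node network
(8 modules of 60 genes linked in a ring through 8 dedicated bridge
genes, plus 6 hubs), a 2000-sample mutation table and gene sets; the
second prints

```
{
  "n_nodes": 494,
  "n_edges": 1874,
  "avg_degree": 7.587044534412955,
  "density": 0.015389542666152039,
  "n_components": 1
}
```

and the third scans every mutated gene, reporting the baseline
mutation-ordered resilience and the high-impact group:

```
wrote 489 rows to sim/impact.tsv (baseline R = 0.310489)
10 high-impact genes (cutoff 0.311681)
```

`sim/impact.tsv` holds one row per mutated gene
(`gene  degree  mutated_samples  R_loo`): `R_loo` is the resilience
recomputed with that gene treated as non-mutated, so genes whose
exclusion *raises* R the most are the ones whose mutation costs the
network most. Here the 10 genes above the cutoff include all 8
planted bridges (`BR0`–`BR7`) — moderate-degree genes invisible to
hub rankings.

The same machinery runs on real data: a two-column edge list of an
interactome union, a `(sample_id, gene)` mutation extract, a gene-set
GMT and a driver-gene catalog (`panresil resilience`, `panresil
memory`, `panresil ora`, `panresil overlap`). Input files are supplied
by the user; nothing is downloaded.

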