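# Methods

## The resilience measure

A node failure is *isolation*: all incident edges are deleted and the
node remains as a size-1 component. The total node count N is
therefore constant along a trajectory, and the fragmentation entropy

S(f) = −(1/ln N) Σᵢ pᵢ ln pᵢ,  pᵢ = nᵢ/N

reaches exactly 1 at f = 1. The logarithm base cancels (the statistic
is a ratio of entropies); natural logs are used internally. S(0) may
exceed 0 on multi-component inputs — such curves are legal and
reported as-is. Resilience is R = 1 − ∫ S df with the composite
trapezoid rule on the grid of removal steps (one point per step,
endpoints f = 0 and f = 1 always present). For a complete graph on N
nodes the curve is available in closed form,
S(k/N) = k/N + ((N−k)/N)·ln(N/(N−k))/ln N, whose trapezoidal integral
gives the maximum attainable R at size N; the continuum limit is
1/2 − 1/(4 ln N) → 1/2. `ideal_max_resilience` evaluates the discrete
form and agrees with a computed complete-graph curve to 1e−12.

### Computation

One curve is computed by processing the removal order in reverse with
a weighted union-find, maintaining T = Σ nᵢ ln nᵢ incrementally so
that S = 1 − T/(N ln N) after every merge. This is O((N+E)·α(N)) per
curve; the hot loop is numba-jitted with a semantically identical
pure-Python fallback. Equality with a naive recount of components
after every deletion is enforced in the test suite to 1e−12 on graphs
up to 200 nodes across mixed densities.

## Failure schemes

* `random` — uniform permutation of nodes.
* `degree`, `clustering`, `custom` — static scores computed on the
  intact network, removed in non-increasing order, ties permuted
  uniformly at random per replicate.
* `degree_adaptive` — the classical adaptive hub attack: after every
  isolation the degrees of the remaining graph are updated and the
  next node of maximal current degree is chosen (lazy-deletion heap,
  ties random). Benchmark "targeted removal" values for standard
  network ensembles are produced with this scheme: on a random regular
  graph the static variant degenerates into a uniform permutation
  (every node ties), whereas the adaptive attack produces the distinct,
  nearly deterministic targeted trajectory those benchmarks report.
  Both schemes are exposed; analyses state which one they use.
* mutation frequency — genes by decreasing count of distinct mutated
  samples, ties random, followed by the non-mutated genes in uniform
  random order.
* neighborhood variant — each step isolates the scheme's next
  not-yet-isolated node *and* all of its currently remaining
  neighbors; f spacing is irregular and the trapezoid rule applies
  unchanged.

Replicate estimates draw per-network and per-replicate child seeds
from a single master seed through `numpy.random.SeedSequence` spawn
keys, making every run bit-reproducible. Mean R and the standard
error of the mean over replicates are reported; two estimates are
compared with a two-sided Welch t test on the per-replicate values
(degenerate zero-variance pairs return p = 1 when equal).

## Matched null models

Given a reference network the four standard comparison families are
parameterized as: complete graph at half the reference size (the
conventional memory-saving benchmark size; full size available),
random regular at d = round(average degree) (decremented if n·d would
be odd), Erdős–Rényi at p = density, Barabási–Albert at
m = min(6, n/2). The BA attachment count does not density-match the
reference — it is the conventional degree-distribution fit — so the
"same density" matching holds for the FC/RR/ER families only.
Generation is delegated to networkx; all generators are validated
against the simple-graph invariants.

## Leave-one-out impact

The scan fixes one baseline schedule (mutation-frequency order plus
random suffix, seeded). For each scored gene the gene is moved from
the prefix into the suffix at a position drawn from a per-gene stream
derived from the master seed and the gene's rank — so results are
independent of which subset of genes is scored, and embarrassingly
parallel execution cannot change them. One replicate per gene is the
default (the mutation-frequency order is almost deterministic at
realistic cohort sizes); averaging over replicates is available.
The degree-control mode replaces the mutated list with the same
number of genes taken by decreasing degree.

### High/low impact separation

The R_loo distribution is split by a peak-symmetry rule: a Gaussian
KDE (Silverman bandwidth by default) is evaluated on a grid; the main
peak position μ is the density-weighted center of the half-height
region around the argmax (the raw argmax of a small-bandwidth KDE
wobbles by a noticeable fraction of the peak width and misplaces the
reflected cutoff); l is the smallest value whose density reaches
`alpha_height` (default 0.05) of the peak height; the cutoff is
μ + (μ − l), i.e. the left flank reflected to the right. Genes above
the cutoff are high impact. For a symmetric unimodal distribution
this flags ≲1% of genes; a continuous right-skewed tail may cross the
cutoff without constituting a separated mode — separation can be
checked by comparing the group boundary gap against the KDE
bandwidth. Both `alpha_height` and the bandwidth rule are exposed;
the group size is sensitive to them, which is inherent to any
cutoff on a density estimate.

## Memory effect

For prefix sizes that are multiples of the group size (default 5),
the top-k most frequently mutated genes are removed first in
frequency order and all remaining nodes uniformly at random; the mean
difference to a fully random baseline sharing the same replicate
seeds, with its s.e.m., traces how much of the resilience deficit is
locked in by the most frequent mutations alone. At prefix 0 the two
arms differ only by seed stream, so the difference is statistically
zero — a calibration check enforced in the tests.

## Degree-tail comparison

Power law vs log-normal on a degree sample, Clauset-style: xmin
minimizes the KS distance of the discrete maximum-likelihood power
law; the comparison is a normalized Vuong log-likelihood-ratio test
with a two-sided p-value, and a model is preferred only below the
significance threshold. Two refinements keep the comparison
identifiable: the log-normal location is constrained to μ ≥ 0 (the
positive log-normal variant — unconstrained, a log-normal with very
negative μ and large σ reproduces any finite power-law tail and the
test can never decide), and xmin candidates must keep at least 25% of
the positive observations (without a floor the scan truncates
non-power-law data until the power law fits, destroying power). Both
are parameters (`min_tail_frac=0` recovers the pure KS scan). With
these defaults the true generator is preferred in ≥90% of seeds at
n = 5000 for both families, which the test suite enforces.

## Over-representation analysis

One-sided (enrichment) Fisher exact tests per term on the 2×2 table
within the background universe — the ORA convention — with
Benjamini–Hochberg adjustment across terms (statsmodels step-up) and
an adjusted-p < 0.05 flag. Terms are intersected with the background
before testing. p-values equal the exact hypergeometric upper-tail
sum to 1e−10; the null type-I rate matches its nominal level when
table sizes make the discrete null near-continuous, and is
conservative (below nominal) otherwise, as any exact discrete test
is. No gene-set database is bundled; users supply GMT files and the
background list.

## Synthetic data

The generator emulates, at desk scale, the structural regime the
analysis targets: dense modules that are internally redundant, joined
*only* through dedicated bridge genes, plus disassortative hubs and a
heavy-tailed mutation-frequency profile.

* Modules (8 × 60 genes by default) are built from 5-cliques plus
  sparse random intra-module edges (p_intra = 0.06). Cliques give
  low-degree nodes high clustering; the random edges make each module
  robust to the removal timing of any single member, so ordinary
  genes have near-zero leave-one-out impact. At much lower p_intra
  the modules lose that redundancy and early-ranked ordinary genes
  acquire structural impact of their own — a different regime from
  the modular, redundant organization being emulated.
* Bridges (8) close a ring through the modules, each linking 4 nodes
  in each of its two modules; each bridge is the unique connector of
  its module pair, so bridge isolation — and only that — accelerates
  global fragmentation. Bridge degree (8) is deliberately moderate:
  invisible to degree rankings.
* Hubs (6, degree 18) attach preferentially to low-degree members of
  a single module (disassortativity without creating inter-module
  shortcuts).
* Mutations: 2000 samples; each sample mutates each gene
  independently with probability 0.008·w(g), where w is log-normal
  (σ = 1). Bridges get w = 4·exp(0.25·Z): boosted enough to land
  mid-ranking (around ranks 30–40 of ~490 mutated genes), with
  variance low enough that they never reach the top handful — the
  planted signal is positional, not frequency-driven.

What passing tests on this generator show: the pipeline detects
*structurally* critical mid-frequency genes against a random
mutational background, end to end (curves → LOO → grouping → ORA on
the planted set). What they do not show: performance on real
interactomes, whose degree tail, clustering profile, module-size
heterogeneity and mutation biases are richer than this construction;
full-data checks require the user-supplied interactome and cohort
files and are reported separately.

## Numerical and interface choices

* Gene identifiers are opaque case-sensitive strings; no symbol
  harmonization.
* Topology scores (degree, clustering, neighbor degree) always refer
  to the intact input network unless a scheme says otherwise.
* Edge lists are whitespace/tab separated, `#` comments allowed;
  duplicate and reversed-duplicate lines collapse; self-loops are
  dropped and counted. The canonical writer sorts endpoints within an
  edge and edges lexicographically, so write→read is the identity on
  (nodes-with-edges, edge set).
* Degenerate inputs: N < 2 rejects the entropy; empty mutation tables
  and empty GMT files warn and return empty containers; an empty
  high-impact group is a result, not an error.
* Benchmark ensembles in the tests and the acceptance script run at
  10 networks × 5 removal orders, sizes at which the grand means are
  stable to ~1e−4 for the random schemes.
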