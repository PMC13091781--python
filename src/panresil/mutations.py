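"""Gene-level somatic mutation tables and mutation-frequency schedules.

A gene counts as mutated in a sample if at least one somatic mutation
affecting it is recorded there; mutation type is deliberately ignored
(missense and loss-of-function alike are node failures), so a
(sample, gene) pair is a binary incidence and duplicate records
collapse downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import Network
from .resilience import RemovalSchedule

__all__ = [
    "MutationTable",
    "MutationCounts",
    "read_mutation_table",
    "gene_mutation_counts",
    "mutation_order_schedule",
]


@dataclass
class MutationTable:
    """Raw (sample_id, gene) incidence records."""
    records: pd.DataFrame  # columns: sample_id, gene

    @property
    def n_samples(self) -> int:
        return int(self.records["sample_id"].nunique())

    @property
    def n_genes(self) -> int:
        return int(self.records["gene"].nunique())

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class MutationCounts:
    """Distinct-mutated-sample count per gene.

    When ``restricted_to_network`` the index covers exactly the genes of
    a network (non-mutated network genes carry count 0).
    """
    counts: pd.Series  # index gene -> mutated_samples
    n_samples: int
    restricted_to_network: bool = False
    network_name: str = ""

    def mutated_genes(self) -> list[str]:
        return list(self.counts.index[self.counts > 0])


def read_mutation_table(path, sample_col: str = "sample_id",
                        gene_col: str = "gene") -> MutationTable:
    """Read a TSV with one row per (sample, gene) mutation record.

    MAF-like extracts are accepted by naming the two relevant columns.
    Duplicate records are retained in storage; they collapse to binary
    incidence in :func:`gene_mutation_counts`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in (sample_col, gene_col) if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing column(s) {missing}; found {list(df.columns)}")
    if df.empty:
        warnings.warn(f"{path}: empty mutation table", stacklevel=2)
    out = df[[sample_col, gene_col]].rename(
        columns={sample_col: "sample_id", gene_col: "gene"})
    return MutationTable(out.reset_index(drop=True))


def gene_mutation_counts(table: MutationTable, net: Network) -> MutationCounts:
    """Per-gene distinct-sample counts restricted to a network.

    Genes absent from the network are dropped (count logged via a
    warning when large); network genes with no mutations get count 0.
    """
    rec = table.records.drop_duplicates()
    per_gene = rec.groupby("gene")["sample_id"].nunique()
    in_net = per_gene.index.isin(set(net.node_ids))
    n_dropped = int((~in_net).sum())
    if n_dropped:
        import logging
        logging.getLogger(__name__).info(
            "gene_mutation_counts: %d mutated gene(s) not in the network "
            "dropped", n_dropped)
    counts = per_gene[in_net].reindex(net.node_ids, fill_value=0).astype(int)
    return MutationCounts(counts, n_samples=table.n_samples,
                          restricted_to_network=True, network_name=net.name)


def mutation_order_schedule(counts: MutationCounts,
                            seed: int | None = None) -> RemovalSchedule:
    """Removal order by decreasing mutation frequency.

    Mutated genes (count > 0) come first, sorted by decreasing
    distinct-sample count with ties permuted uniformly at random;
    non-mutated network genes follow in uniform random order.  The
    schedule covers every network gene exactly once.
    """
    if not counts.restricted_to_network:
        raise ValueError("counts must be restricted to a network first")
    rng = np.random.default_rng(seed)
    genes = np.asarray(counts.counts.index)
    vals = counts.counts.to_numpy()
    n = genes.size
    tie_key = rng.random(n)
    order = np.lexsort((tie_key, -vals))
    mutated_first = order[vals[order] > 0]
    suffix = order[vals[order] == 0]
    rng.shuffle(suffix)  # uniform order for the non-mutated background
    full = np.concatenate([mutated_first, suffix])
    return RemovalSchedule([str(g) for g in genes[full]],
                           scheme="mutation_frequency", seed=seed)
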