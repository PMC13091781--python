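"""Over-representation analysis: Fisher's exact test + BH correction.

Each gene-set term is tested with a one-sided (enrichment) Fisher exact
test on the 2x2 table (query∩set, query∖set, set∖query, rest), all
counts taken within the background universe; p-values are adjusted
across terms with the Benjamini–Hochberg step-up procedure and flagged
at adjusted p < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["GeneSetCollection", "read_gmt", "ora_test", "bh_adjust"]


@dataclass
class GeneSetCollection:
    """Named gene sets (term -> set) with an optional source label."""
    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    source: str = ""

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path, source: str = "") -> GeneSetCollection:
    """Read a GMT file: term <tab> description <tab> gene ...

    Duplicate genes within a set are collapsed; a line with fewer than
    three fields is a parse error naming the line number.
    """
    sets: dict[str, set[str]] = {}
    desc: dict[str, str] = {}
    n_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            n_lines += 1
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT lines need >= 3 "
                    f"tab-separated fields, got {len(parts)}")
            term = parts[0]
            if term in sets:
                raise ValueError(f"{path}: line {lineno}: duplicate term "
                                 f"{term!r}")
            genes = {g for g in parts[2:] if g}
            if not genes:
                raise ValueError(f"{path}: line {lineno}: empty gene set")
            sets[term] = genes
            desc[term] = parts[1]
    if n_lines == 0:
        warnings.warn(f"{path}: empty GMT file", stacklevel=2)
    return GeneSetCollection(sets, desc, source=source or str(path))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj


def ora_test(query: set[str], background: set[str],
             collection: GeneSetCollection,
             alpha: float = 0.05) -> pd.DataFrame:
    """Over-representation of ``query`` in each term of ``collection``.

    Returns a DataFrame sorted by p-value with columns term, overlap_k,
    set_size_K, p_value, adj_p, overlap ("k/K") and significant
    (adj_p < ``alpha``).  Terms are intersected with the background
    before testing; terms with no background gene are dropped.
    """
    query, background = set(query), set(background)
    if not query:
        raise ValueError("empty query gene set")
    if not query <= background:
        extra = sorted(query - background)[:5]
        raise ValueError(f"query must be a subset of the background "
                         f"(e.g. {extra} missing)")
    n_bg = len(background)
    n_q = len(query)
    rows = []
    for term, genes in collection.sets.items():
        in_bg = genes & background
        big_k = len(in_bg)
        if big_k == 0:
            continue
        k = len(query & in_bg)
        # one-sided Fisher on [[k, n_q - k], [K - k, (N - K) - (n_q - k)]]
        table = [[k, n_q - k], [big_k - k, n_bg - big_k - (n_q - k)]]
        _, p = stats.fisher_exact(table, alternative="greater")
        rows.append({"term": term, "overlap_k": k, "set_size_K": big_k,
                     "p_value": float(p)})
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["adj_p"] = bh_adjust(df["p_value"].to_numpy())
    df["overlap"] = df["overlap_k"].astype(str) + "/" + df["set_size_K"].astype(str)
    df["significant"] = df["adj_p"] < alpha
    return df.sort_values(["p_value", "term"]).reset_index(drop=True)
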