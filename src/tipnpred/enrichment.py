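"""Gene-set over-representation filtering of candidate genes and their variants.

Candidate genes from the association stages are tested against user-supplied gene
sets (GMT format) with the one-sided hypergeometric tail test; sets below a
configurable p threshold are retained, and candidate genes/SNVs survive only if
they belong to at least one retained set.  The universe defaults to all genes
carrying at least one tested variant.  Raw set p-values are used by default;
Benjamini-Hochberg correction across sets is optional.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "ora_hypergeometric",
    "enrich",
    "enrich_and_filter",
]


@dataclass
class GeneSetCollection:
    sets: dict[str, set[str]]
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = set().union(*self.sets.values()) if self.sets else set()
        # harmonize: membership outside the universe cannot contribute to overlap
        self.sets = {k: (v & self.universe) for k, v in self.sets.items()}
        self.sets = {k: v for k, v in self.sets.items() if v}


def read_gmt(path: str, universe: set[str] | None = None) -> GeneSetCollection:
    """Load a GMT gene-set file (name, description, tab-separated members)."""
    from gseapy import read_gmt as _read_gmt

    raw = _read_gmt(path)
    return GeneSetCollection(
        sets={k: set(v) for k, v in raw.items()}, universe=universe or set()
    )


def ora_hypergeometric(query: set[str], gene_set: set[str], universe: set[str]) -> float:
    """Upper-tail hypergeometric probability of at least the observed overlap.

    An empty query returns 1.
    """
    q = set(query) & set(universe)
    s = set(gene_set) & set(universe)
    if not q:
        return 1.0
    if len(universe) < len(q):
        raise ValueError("query larger than universe")
    overlap = len(q & s)
    if overlap == 0:
        return 1.0
    # P(X >= overlap), X ~ Hypergeom(M=|U|, K=|set|, n=|query|)
    return float(stats.hypergeom.sf(overlap - 1, len(universe), len(s), len(q)))


def enrich(
    candidates: set[str],
    collection: GeneSetCollection,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """ORA p-value for every set; returns (set, overlap, set_size, p[, p_adj])."""
    universe = collection.universe
    rows = []
    for name in sorted(collection.sets):
        members = collection.sets[name]
        p = ora_hypergeometric(candidates, members, universe)
        rows.append((name, len(set(candidates) & members), len(members), p))
    df = pd.DataFrame(rows, columns=["set", "overlap", "set_size", "p"])
    if bh_correct and len(df):
        p = df["p"].to_numpy()
        order = np.argsort(p)
        m = len(p)
        adj = np.empty(m)
        running = 1.0
        for rank_idx in range(m - 1, -1, -1):
            i = order[rank_idx]
            running = min(running, p[i] * m / (rank_idx + 1))
            adj[i] = running
        df["p_adj"] = adj
    return df


def enrich_and_filter(
    candidate_genes: set[str],
    collection: GeneSetCollection,
    threshold: float,
    snv_gene_map: dict[str, set[str]] | None = None,
    bh_correct: bool = False,
) -> tuple[set[str], set[str], set[str], pd.DataFrame]:
    """Keep sets with ORA p < threshold, genes in >= 1 kept set, and SNVs mapped to
    a kept gene.

    Returns (enriched set names, retained genes, retained SNVs, enrichment table).
    An empty retained collection is a valid outcome.
    """
    table = enrich(candidate_genes, collection, bh_correct=bh_correct)
    crit = table["p_adj"] if bh_correct and "p_adj" in table else table["p"]
    kept_sets = set(table.loc[crit < threshold, "set"])
    table = table.assign(kept=table["set"].isin(kept_sets))
    kept_gene_pool = (
        set().union(*(collection.sets[s] for s in kept_sets)) if kept_sets else set()
    )
    retained_genes = set(candidate_genes) & kept_gene_pool
    retained_snvs: set[str] = set()
    if snv_gene_map:
        retained_snvs = {
            v for v, genes in snv_gene_map.items() if genes & retained_genes
        }
    return kept_sets, retained_genes, retained_snvs, table
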