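"""Over-representation testing of a gene list against named gene sets.

The test is the one-sided hypergeometric upper tail (Fisher's exact test,
enrichment direction): for a universe of N genes, a set with K members in
the universe and a query of n genes with k in the set, p = P(X >= k) under
sampling without replacement. P-values are Benjamini-Hochberg adjusted
across sets.
"""

from __future__ import annotations

import pandas as pd
from scipy.stats import hypergeom

from .de import bh_adjust
from .io import GeneSetCollection

ENRICHMENT_COLUMNS = [
    "set_name",
    "overlap",
    "query_size",
    "set_size",
    "universe_size",
    "fold_enrichment",
    "p_value",
    "q_value",
]


def hypergeom_upper_tail(overlap: int, universe: int, set_size: int, query: int) -> float:
    """P(X >= overlap) for X ~ Hypergeometric(universe, set_size, query)."""
    return float(hypergeom.sf(overlap - 1, universe, set_size, query))


def overrepresentation(
    query_genes, gene_sets: GeneSetCollection, universe_genes
) -> pd.DataFrame:
    """Test every gene set for over-representation of the query, sorted by p."""
    universe = set(universe_genes)
    query = set(query_genes)
    if not query:
        raise ValueError("query gene list is empty")
    if not universe:
        raise ValueError("universe gene list is empty")
    stray = query - universe
    if stray:
        raise ValueError(f"query gene {sorted(stray)[0]!r} is not in the universe")
    rows = []
    for name, members in gene_sets.sets.items():
        in_universe = members & universe
        overlap = len(query & in_universe)
        n, big_k, big_n = len(query), len(in_universe), len(universe)
        p = hypergeom_upper_tail(overlap, big_n, big_k, n)
        fold = (
            (overlap / n) / (big_k / big_n) if big_k > 0 else float("nan")
        )
        rows.append(
            {
                "set_name": name,
                "overlap": overlap,
                "query_size": n,
                "set_size": big_k,
                "universe_size": big_n,
                "fold_enrichment": fold,
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS[:-1])
    out["q_value"] = bh_adjust(out["p_value"].to_numpy()) if len(out) else []
    return out.sort_values("p_value", kind="stable").reset_index(drop=True)
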