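"""Hypergeometric pathway over-representation with BH FDR control.

For a query gene set drawn from a universe of N genes, a pathway with M
member genes in the universe, and an overlap of x genes with the n-gene
query, significance is the upper hypergeometric tail P(X >= x). The default
universe is all genes of the analyzed matrix after filtering; results always
carry the universe size actually used.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats as st

from ._stats import bh_qvalues
from .io import GeneSetCollection

__all__ = ["hypergeom_enrichment"]


def hypergeom_enrichment(query, sets: GeneSetCollection, universe,
                         fdr: float = 0.10) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation per pathway.

    ``query`` must be a subset of ``universe``; each pathway is intersected
    with the universe before testing. BH adjustment across pathways;
    significant at q < fdr.
    """
    query, universe = set(query), set(universe)
    if not universe:
        raise ValueError("empty universe")
    if not query:
        raise ValueError("empty query set")
    if not query <= universe:
        extra = sorted(query - universe)[:5]
        raise ValueError(f"query gene(s) outside universe: {extra}")
    N, n = len(universe), len(query)
    rows = []
    for pid, (name, genes) in sets.items():
        members = genes & universe
        M = len(members)
        x = len(members & query)
        # P(X >= x) for X ~ Hypergeom(N, M, n); sf(x-1) is exact, x=0 gives 1
        p = float(st.hypergeom.sf(x - 1, N, M, n)) if x > 0 else 1.0
        rows.append((pid, name, x, M, n, N, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["pathway_id", "name", "overlap",
                                      "pathway_size", "query_size",
                                      "universe_size", "p_value"]
                       ).set_index("pathway_id")
    out["q_value"] = bh_qvalues(out["p_value"])
    out["significant"] = out["q_value"] < fdr
    return out.sort_values("p_value")
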