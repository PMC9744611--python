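"""Hypergeometric over-representation analysis and hub-gene ranking.

ORA tests a gene list against user-supplied gene sets (GMT) with the
upper-tail hypergeometric probability and BH adjustment across sets; hub
genes are the top-k nodes by degree of a confidence-filtered interaction
network.
"""

from __future__ import annotations

import logging

import networkx as nx
import pandas as pd
from scipy import stats

from .degs import bh_adjust

logger = logging.getLogger(__name__)

ORA_FDR_CUTOFF = 0.2
CONFIDENCE_THRESHOLD = 0.7
MIN_SET_SIZE = 3


def hypergeom_ora(
    hits,
    sets: dict[str, set[str]],
    universe,
    fdr_cutoff: float = ORA_FDR_CUTOFF,
    min_set_size: int = MIN_SET_SIZE,
) -> pd.DataFrame:
    """Over-representation of ``hits`` in each gene set, against ``universe``.

    For a set with K members in the universe of size N and a hit list of size
    n, the p-value is P(X >= k) for hypergeometric X, k the observed overlap.
    Sets with fewer than ``min_set_size`` members in the universe are skipped
    (logged).  Returns rows sorted by p with columns
    set, k, K, n, N, p, fdr, significant.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("hypergeom_ora: empty universe")
    hits = set(hits)
    outside = hits - universe
    if outside:
        logger.info("hypergeom_ora: dropping %d hit(s) outside the universe", len(outside))
    hits &= universe
    if not hits:
        raise ValueError("hypergeom_ora: empty hit list after restriction to the universe")
    n, n_universe = len(hits), len(universe)
    rows = []
    for name, members in sets.items():
        members_in = members & universe
        if len(members_in) < min_set_size:
            logger.info("hypergeom_ora: skipping set %r (%d member(s) in universe)", name, len(members_in))
            continue
        k = len(hits & members_in)
        big_k = len(members_in)
        p = float(stats.hypergeom.sf(k - 1, n_universe, big_k, n))
        rows.append((name, k, big_k, n, n_universe, p))
    if not rows:
        raise ValueError("hypergeom_ora: no testable gene sets after universe restriction")
    table = pd.DataFrame(rows, columns=["set", "k", "K", "n", "N", "p"])
    table["fdr"] = bh_adjust(table["p"])
    table["significant"] = table["fdr"] < fdr_cutoff
    return table.sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)


def hub_genes_by_degree(
    edges: pd.DataFrame,
    confidence_threshold: float = CONFIDENCE_THRESHOLD,
    top_k: int = 50,
) -> pd.DataFrame:
    """Top-k genes by degree after confidence filtering.

    ``edges`` has columns gene1, gene2, confidence.  Self-loops are removed;
    duplicate edges collapse to their maximum confidence.  Ranking is by
    degree descending, ties broken by gene symbol ascending.
    """
    kept = edges.loc[edges["confidence"] >= confidence_threshold]
    kept = kept.loc[kept["gene1"] != kept["gene2"]]
    graph = nx.Graph()
    for g1, g2, conf in kept.itertuples(index=False):
        if graph.has_edge(g1, g2):
            graph[g1][g2]["confidence"] = max(graph[g1][g2]["confidence"], conf)
        else:
            graph.add_edge(g1, g2, confidence=conf)
    if graph.number_of_edges() == 0:
        raise ValueError(
            f"hub_genes_by_degree: no edges at confidence >= {confidence_threshold}"
        )
    ranked = sorted(graph.degree, key=lambda item: (-item[1], item[0]))[:top_k]
    return pd.DataFrame(ranked, columns=["gene", "degree"])
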