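"""Maximal clique centrality (MCC) hub ranking of PPI networks.

MCC(v) = sum over the maximal cliques C containing v of (|C| - 1)!.
Nodes that sit in many and/or large fully connected neighbourhoods score
highest; an isolated node forms its own singleton maximal clique and scores
0! = 1, keeping every score positive.  Ranks are deterministic: descending
MCC, ties broken by descending degree, then lexicographic node id.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import networkx as nx
import pandas as pd

from .io_core import LepinetError

#: refuse exact clique enumeration beyond this size; extract a subnetwork
#: (e.g. one co-expression module) first.
MAX_NODES = 20_000
MAX_EDGES = 2_000_000


@dataclass
class HubScoreTable:
    """Per-node MCC score, degree and deterministic rank."""

    scores: pd.DataFrame  # columns: node, mcc, degree, rank

    def top(self, k: int) -> list[str]:
        if k < 1:
            raise LepinetError("k must be >= 1")
        ordered = self.scores.sort_values("rank")
        return list(ordered["node"].head(k))


def maximal_cliques(g: nx.Graph) -> list[frozenset]:
    """All maximal cliques (Bron-Kerbosch with pivoting, via networkx).

    Isolated nodes yield singleton cliques.
    """
    if g.number_of_nodes() > MAX_NODES or g.number_of_edges() > MAX_EDGES:
        raise LepinetError(
            "graph too large for exact clique enumeration; "
            "extract a module subnetwork first"
        )
    if any(g.has_edge(v, v) for v in g):
        raise LepinetError("graph must be simple (self-loop found)")
    return [frozenset(c) for c in nx.find_cliques(g)]


def mcc_scores(g: nx.Graph) -> HubScoreTable:
    """Score every node by maximal clique centrality."""
    nodes = sorted(g.nodes, key=str)
    if not nodes:
        return HubScoreTable(pd.DataFrame(columns=["node", "mcc", "degree", "rank"]))
    mcc = dict.fromkeys(nodes, 0)
    for clique in maximal_cliques(g):
        w = factorial(len(clique) - 1)
        for v in clique:
            mcc[v] += w
    df = pd.DataFrame(
        {
            "node": nodes,
            "mcc": [mcc[v] for v in nodes],
            "degree": [g.degree(v) for v in nodes],
        }
    )
    df = df.sort_values(
        ["mcc", "degree", "node"], ascending=[False, False, True], kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = df.index + 1
    return HubScoreTable(df)


def top_hubs(table: HubScoreTable, k: int) -> list[str]:
    """First ``k`` nodes by rank (fewer if the graph is smaller)."""
    return table.top(k)
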