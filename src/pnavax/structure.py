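"""Structural measures on the binarized alter–alter graph (ego removed).

Measures follow the usual egocentric-network conventions: density is the
share of present ties among the :math:`\\binom{n}{2}` possible ones,
fragmentation is indexed by the number of connected components (isolates
count as stand-alone components), and node importance by Freeman shortest-path
betweenness normalized by :math:`\\binom{n-1}{2}` so that scores are
comparable across networks of different size.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

from .derive import binarize_tie
from .errors import DegenerateInputError
from .network_model import PersonalNetwork, StudyData

__all__ = [
    "build_alter_graph",
    "density",
    "component_count",
    "normalized_betweenness",
    "structure_tables",
]


def build_alter_graph(network: PersonalNetwork) -> nx.Graph:
    """Binarized simple undirected alter graph with deterministic node order."""
    g = nx.Graph()
    g.add_nodes_from(sorted(network.alter_ids()))
    for tie in network.ties:
        if binarize_tie(tie.strength):
            g.add_edge(tie.a, tie.b)
    return g


def density(graph: nx.Graph) -> float:
    """Present ties over possible ties, m / C(n, 2); needs n >= 2."""
    n = graph.number_of_nodes()
    if n < 2:
        raise DegenerateInputError(f"density undefined for n={n} nodes")
    return graph.number_of_edges() / (n * (n - 1) / 2)


def component_count(graph: nx.Graph) -> int:
    """Number of connected components; isolates are their own components."""
    return nx.number_connected_components(graph)


def normalized_betweenness(graph: nx.Graph) -> dict:
    """Freeman betweenness divided by C(n-1, 2); zero on graphs with n <= 2.

    Computed on the possibly disconnected graph; pairs with no connecting
    path contribute nothing.
    """
    if graph.number_of_nodes() <= 2:
        return {v: 0.0 for v in graph.nodes}
    return nx.betweenness_centrality(graph, normalized=True)


def structure_tables(study: StudyData) -> tuple:
    """Per-ego structural summary and per-alter betweenness table.

    Returns ``(ego_df, alter_df)`` with columns
    ``(ego_id, size, density, components)`` and
    ``(ego_id, alter_id, betweenness)``.
    """
    ego_rows = []
    alter_rows = []
    for net in study.networks:
        g = build_alter_graph(net)
        n = g.number_of_nodes()
        ego_rows.append({
            "ego_id": net.ego_id,
            "size": n,
            "density": density(g) if n >= 2 else float("nan"),
            "components": component_count(g),
        })
        bet = normalized_betweenness(g)
        for alter_id in sorted(g.nodes):
            alter_rows.append({
                "ego_id": net.ego_id,
                "alter_id": alter_id,
                "betweenness": bet[alter_id],
            })
    return pd.DataFrame(ego_rows), pd.DataFrame(alter_rows)
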