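"""Node centrality indices and edge domain classification.

Centralities follow standard psychometric-network conventions for a
weighted, signed partial-correlation network:

- strength: sum of absolute edge weights at the node;
- expected influence: sum of signed edge weights (one-step);
- closeness: 1 / (sum of shortest-path distances to all other nodes),
  with edge lengths 1/|w| over nonzero edges; a node with any unreachable
  partner gets closeness 0;
- betweenness: unnormalized shortest-path counting (Brandes), equal-length
  ties split fractionally.
"""

from __future__ import annotations

import os

import networkx as nx
import numpy as np
import pandas as pd

from .errors import SpeechNetError
from .ggm import NetworkModel

__all__ = ["node_centralities", "classify_edges"]


def _length_graph(net: NetworkModel) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(range(net.p))
    iu, ju = np.triu_indices(net.p, k=1)
    for i, j in zip(iu, ju):
        w = net.weights[i, j]
        if w != 0.0:
            G.add_edge(int(i), int(j), length=1.0 / abs(w))
    return G


def node_centralities(net: NetworkModel) -> pd.DataFrame:
    """Betweenness, closeness, strength, and expected influence per node.

    Isolated nodes receive 0 for every index. Rows follow network node
    order (ready for a per-variable centrality table).
    """
    p = net.p
    W = net.weights
    strength = np.abs(W).sum(axis=1)
    expected_influence = W.sum(axis=1)

    G = _length_graph(net)
    btw = nx.betweenness_centrality(G, weight="length", normalized=False)
    closeness = np.zeros(p)
    for i, dists in nx.all_pairs_dijkstra_path_length(G, weight="length"):
        if len(dists) < p:  # some node unreachable from i
            continue
        total = sum(d for j, d in dists.items() if j != i)
        if total > 0:
            closeness[i] = 1.0 / total
    return pd.DataFrame(
        {
            "betweenness": [btw[i] for i in range(p)],
            "closeness": closeness,
            "strength": strength,
            "expected_influence": expected_influence,
        },
        index=pd.Index(net.nodes, name="node"),
    )


def classify_edges(net: NetworkModel) -> dict:
    """Split nonzero edges into within-domain and cross-domain sets.

    Returns within-domain counts per domain, the cross-domain count, and
    the cross-domain edge list; counts sum to the network's nonzero edge
    count.
    """
    for node in net.nodes:
        if node not in net.domains:
            raise SpeechNetError(f"node {node!r} has no domain label")
    within: dict[str, int] = {}
    cross = 0
    cross_edges: list[tuple[str, str, float]] = []
    for a, b, w in net.edge_list():
        da, db = net.domains[a], net.domains[b]
        if da == db:
            within[da] = within.get(da, 0) + 1
        else:
            cross += 1
            cross_edges.append((a, b, w))
    return {
        "within_domain": within,
        "cross_domain": cross,
        "cross_domain_edges": cross_edges,
    }


def write_centrality_csv(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write the per-node centrality table (node, betweenness, closeness,
    strength, expected influence)."""
    table.to_csv(path)
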