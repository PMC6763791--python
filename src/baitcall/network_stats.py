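"""Local summary statistics of a protein-interaction network.

Operates on a user-supplied undirected edge list (e.g. an export from a
functional-association database). Reported statistics are the locally
computable ones: node and edge counts, average degree 2E/N, average local
clustering coefficient (nodes with degree < 2 contribute 0 and are
included in the mean — the common convention), and isolated-node count.
An explicit node set may be supplied so that proteins without any known
interaction still count as (isolated) nodes. Values are reported at full
precision; any truncation is left to the report layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .errors import DataError
from .quant_io import EdgeList

DEFAULT_MIN_SCORE = 0.400


@dataclass
class GraphSummary:
    n_nodes: int
    n_edges: int
    average_degree: float  # 2E/N
    average_local_clustering: float
    n_isolated: int


def filter_edges_by_score(edges: EdgeList, min_score: float = DEFAULT_MIN_SCORE) -> EdgeList:
    """Keep edges whose confidence score is >= min_score (closed bound)."""
    if edges.scores is None:
        raise DataError("edge list has no score column; cannot filter by score")
    kept = [
        (e, s) for e, s in zip(edges.edges, edges.scores) if s >= min_score
    ]
    return EdgeList(edges=[e for e, _ in kept], scores=[s for _, s in kept])


def graph_summary(edges: EdgeList, nodes: set[str] | None = None) -> GraphSummary:
    """Summarize the undirected simple graph spanned by an edge list.

    ``nodes``, when given, is the full node set; edges touching nodes
    outside it raise :class:`~baitcall.errors.DataError`.
    """
    g = nx.Graph()
    if nodes is not None:
        outside = edges.nodes() - set(nodes)
        if outside:
            raise DataError(f"edge references node(s) outside node set: {sorted(outside)[:5]}")
        g.add_nodes_from(nodes)
    g.add_edges_from(edges.edges)
    n, e = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        return GraphSummary(0, 0, 0.0, 0.0, 0)
    clustering = nx.average_clustering(g, count_zeros=True)
    return GraphSummary(
        n_nodes=n,
        n_edges=e,
        average_degree=2.0 * e / n,
        average_local_clustering=float(clustering),
        n_isolated=sum(1 for _, d in g.degree() if d == 0),
    )
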