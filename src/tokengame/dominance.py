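"""The directed winner->loser dominance relation and its global metrics.

The dominance graph keeps, per unordered pair, only the most recent
contest outcome: a decisive contest sets the edge winner->loser
(replacing any previous direction), a draw clears the pair's edge.  There
is therefore at most one edge per pair and never a mutual edge.

Path-length metrics use the undirected view of this relation; hierarchy
(global reaching centrality) uses the directed view.
"""

from __future__ import annotations

from typing import Dict, FrozenSet, Iterable, Tuple

import networkx as nx

from .token_game import ContestResult, Outcome

__all__ = [
    "DominanceGraph",
    "update_dominance",
    "average_shortest_path",
    "global_reaching_centrality",
]


class DominanceGraph:
    """Directed winner->loser relation with last-contest-wins semantics."""

    def __init__(self, nodes: Iterable = ()):  # noqa: D107
        self._nodes: list = list(dict.fromkeys(nodes))
        self._node_set = set(self._nodes)
        # frozenset({a, b}) -> (winner, loser)
        self._edges: Dict[FrozenSet, Tuple] = {}

    @property
    def nodes(self) -> list:
        return list(self._nodes)

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def edges(self) -> list:
        """Directed (winner, loser) pairs, one per dominated pair."""
        return list(self._edges.values())

    @property
    def edge_density(self) -> float:
        n = self.n_nodes
        return self.n_edges / (n * (n - 1) / 2) if n > 1 else 0.0

    def has_node(self, node) -> bool:
        return node in self._node_set

    def add_node(self, node) -> None:
        if node not in self._node_set:
            self._nodes.append(node)
            self._node_set.add(node)

    def update(self, result: ContestResult) -> None:
        """Apply one contest: decisive sets/overwrites the edge, draw clears it."""
        if result.first not in self._node_set or result.second not in self._node_set:
            raise KeyError(
                f"unknown competitor in contest ({result.first}, {result.second})"
            )
        key = frozenset((result.first, result.second))
        if result.outcome is Outcome.DRAW:
            self._edges.pop(key, None)
        elif result.outcome is Outcome.FIRST_WINS:
            self._edges[key] = (result.first, result.second)
        else:
            self._edges[key] = (result.second, result.first)

    def set_edge(self, winner, loser) -> None:
        """Directly assert winner dominates loser (adds missing nodes)."""
        if winner == loser:
            raise ValueError(f"self-dominance on node {winner!r}")
        self.add_node(winner)
        self.add_node(loser)
        self._edges[frozenset((winner, loser))] = (winner, loser)

    @classmethod
    def from_edges(cls, edges: Iterable, nodes: Iterable = ()) -> "DominanceGraph":
        graph = cls(nodes)
        for winner, loser in edges:
            graph.set_edge(winner, loser)
        return graph

    def copy(self) -> "DominanceGraph":
        new = DominanceGraph(self._nodes)
        new._edges = dict(self._edges)
        return new

    def to_directed(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self._nodes)
        g.add_edges_from(self._edges.values())
        return g

    def to_undirected(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self._nodes)
        g.add_edges_from(self._edges.values())
        return g

    def __eq__(self, other) -> bool:
        if not isinstance(other, DominanceGraph):
            return NotImplemented
        return (
            set(self._nodes) == set(other._nodes) and self._edges == other._edges
        )


def update_dominance(graph: DominanceGraph, result: ContestResult) -> DominanceGraph:
    """Functional-style wrapper around :meth:`DominanceGraph.update`."""
    graph.update(result)
    return graph


def average_shortest_path(graph: DominanceGraph) -> float:
    """Mean undirected geodesic length over all connected node pairs.

    Edges count as unit-length undirected links; pairs lying in different
    components are excluded from the mean.
    """
    if graph.n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    g = graph.to_undirected()
    total = 0
    n_pairs = 0
    for component in nx.connected_components(g):
        if len(component) < 2:
            continue
        sub = g.subgraph(component)
        for _, lengths in nx.all_pairs_shortest_path_length(sub):
            total += sum(lengths.values())
            n_pairs += len(lengths) - 1
    if n_pairs == 0:
        raise ValueError("empty relation: no connected pair of nodes")
    # each unordered pair counted twice
    return total / n_pairs


def global_reaching_centrality(graph: DominanceGraph) -> float:
    """Hierarchy index from the spread of directed reachability.

    Local reaching centrality C_R(i) is the fraction of other nodes
    reachable from i along directed edges; the global index is
    ``sum_i (C_Rmax - C_R(i)) / (N - 1)``: 1 for a perfect out-star,
    0 when every node reaches equally (e.g. a cycle, or no edges).
    """
    if graph.n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if graph.n_edges == 0:
        return 0.0
    return float(nx.global_reaching_centrality(graph.to_directed(), normalized=True))
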