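"""Triad motif census of dominance graphs.

Dominance relations (no mutual edges, no self-loops) admit five directed
three-node motifs:

- ``dd`` double dominant: one node beats the other two (out-star),
- ``ds`` double subordinate: one node loses to the other two (in-star),
- ``pa`` pass-along: a two-edge chain A -> B -> C,
- ``tr`` transitive: A beats B and C, and B beats C,
- ``cy`` cycle: A -> B -> C -> A.

Triples holding fewer than two edges carry no motif and are tallied as
``uncounted`` so that counts over all C(n, 3) triples are complete.

The census is computed in closed form from degree sequences and triangle
counts, which keeps it fast on hundreds of nodes: writing ``o_i``/``n_i``
for out/in degree and A for the adjacency matrix,

    cy = trace(A^3) / 3
    tr = trace((A + A^T)^3) / 6 - cy
    dd = sum_i C(o_i, 2) - tr
    ds = sum_i C(n_i, 2) - tr
    pa = sum_i o_i * n_i - tr - 3 * cy

since each transitive triangle contains exactly one out-pair, one
in-pair and one through-node, and each cycle three through-nodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .dominance import DominanceGraph

__all__ = [
    "MOTIFS",
    "TriadCensus",
    "classify_triad",
    "census",
    "census_from_edges",
    "motif_pattern",
    "compare_variants",
]

MOTIFS = ("dd", "ds", "pa", "tr", "cy")


@dataclass(frozen=True)
class TriadCensus:
    """Counts of the five dominance motifs over all node triples."""

    dd: int
    ds: int
    pa: int
    tr: int
    cy: int
    n_triples: int
    n_uncounted: int

    @property
    def counts(self) -> Dict[str, int]:
        return {m: getattr(self, m) for m in MOTIFS}

    @property
    def n_counted(self) -> int:
        return self.dd + self.ds + self.pa + self.tr + self.cy

    @property
    def proportions(self) -> Dict[str, float]:
        """Motif shares among counted (>= 2 edge) triples; NaN if none."""
        total = self.n_counted
        if total == 0:
            return {m: float("nan") for m in MOTIFS}
        return {m: getattr(self, m) / total for m in MOTIFS}

    def __post_init__(self) -> None:
        values = [self.dd, self.ds, self.pa, self.tr, self.cy, self.n_uncounted]
        if any(v < 0 for v in values):
            raise ValueError("motif counts must be non-negative")
        if sum(values) != self.n_triples:
            raise ValueError(
                "census incomplete: motif counts + uncounted != C(n, 3)"
            )


def classify_triad(edges: Iterable[Tuple]) -> str:
    """Classify the induced edge set among exactly three nodes.

    Returns one of ``dd``, ``ds``, ``pa``, ``tr``, ``cy`` or
    ``uncounted`` (fewer than two edges).  Mutual edges are not a valid
    dominance relation and raise.
    """
    edge_set = set(tuple(e) for e in edges)
    for a, b in edge_set:
        if a == b:
            raise ValueError(f"invalid dominance relation: self-loop on {a!r}")
        if (b, a) in edge_set:
            raise ValueError(
                f"invalid dominance relation: mutual edge between {a!r} and {b!r}"
            )
    if len(edge_set) < 2:
        return "uncounted"
    out_deg: Dict = {}
    in_deg: Dict = {}
    for a, b in edge_set:
        out_deg[a] = out_deg.get(a, 0) + 1
        in_deg[b] = in_deg.get(b, 0) + 1
    if len(edge_set) == 2:
        if max(out_deg.values()) == 2:
            return "dd"
        if max(in_deg.values()) == 2:
            return "ds"
        return "pa"
    # three edges among three nodes: a tournament
    return "tr" if max(out_deg.values()) == 2 else "cy"


def _adjacency(graph) -> Tuple[np.ndarray, int]:
    if isinstance(graph, DominanceGraph):
        nodes = graph.nodes
        edges = graph.edges()
    else:  # networkx DiGraph or similar
        nodes = list(graph.nodes())
        edges = list(graph.edges())
    n = len(nodes)
    index = {node: k for k, node in enumerate(nodes)}
    a = np.zeros((n, n), dtype=np.int64)
    for winner, loser in edges:
        if winner == loser:
            raise ValueError(f"invalid dominance relation: self-loop on {winner!r}")
        a[index[winner], index[loser]] = 1
    if np.any(a & a.T):
        w, l = np.argwhere(a & a.T)[0]
        raise ValueError(
            "invalid dominance relation: mutual edge between "
            f"{nodes[w]!r} and {nodes[l]!r}"
        )
    return a, n


def census(graph) -> TriadCensus:
    """Motif census of a dominance graph over all C(n, 3) node triples."""
    a, n = _adjacency(graph)
    if n < 3:
        raise ValueError("too few nodes: census needs n >= 3")
    out_deg = a.sum(axis=1)
    in_deg = a.sum(axis=0)
    u = a + a.T
    cy = int(np.trace(a @ a @ a)) // 3
    triangles = int(np.trace(u @ u @ u)) // 6
    tr = triangles - cy
    dd = int((out_deg * (out_deg - 1) // 2).sum()) - tr
    ds = int((in_deg * (in_deg - 1) // 2).sum()) - tr
    pa = int((out_deg * in_deg).sum()) - tr - 3 * cy
    n_triples = comb(n, 3)
    n_uncounted = n_triples - (dd + ds + pa + tr + cy)
    return TriadCensus(
        dd=dd, ds=ds, pa=pa, tr=tr, cy=cy,
        n_triples=n_triples, n_uncounted=n_uncounted,
    )


def census_from_edges(edges: Iterable[Tuple], nodes: Iterable = ()) -> TriadCensus:
    """Census of a bare winner->loser edge list (e.g. empirical data)."""
    graph = DominanceGraph(nodes)
    seen = set()
    for winner, loser in edges:
        if (loser, winner) in seen:
            raise ValueError(
                f"invalid dominance relation: mutual edge between "
                f"{winner!r} and {loser!r}"
            )
        seen.add((winner, loser))
        graph.set_edge(winner, loser)
    return census(graph)


def motif_pattern(censuses: Sequence[TriadCensus]) -> pd.DataFrame:
    """Summarize motif counts and proportions across replicates.

    Returns a tidy frame with one row per (motif, measure) holding the
    replicate mean, 2nd/3rd quartile band and percentile 95% CI —
    ``measure`` is ``count`` or ``proportion`` (share of counted
    triples).
    """
    censuses = list(censuses)
    if len(censuses) < 2:
        raise ValueError("no replicates: need at least 2 censuses")
    rows = []
    for measure in ("count", "proportion"):
        for motif in MOTIFS:
            if measure == "count":
                values = np.array([c.counts[motif] for c in censuses], dtype=float)
            else:
                values = np.array([c.proportions[motif] for c in censuses])
            rows.append(
                {
                    "motif": motif,
                    "measure": measure,
                    "mean": float(np.nanmean(values)),
                    "q25": float(np.nanpercentile(values, 25)),
                    "q75": float(np.nanpercentile(values, 75)),
                    "ci_low": float(np.nanpercentile(values, 2.5)),
                    "ci_high": float(np.nanpercentile(values, 97.5)),
                }
            )
    return pd.DataFrame(rows)


def _holm(p_values: np.ndarray) -> np.ndarray:
    order = np.argsort(p_values)
    m = len(p_values)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p_values[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted


def compare_variants(
    censuses_a: Sequence[TriadCensus], censuses_b: Sequence[TriadCensus]
) -> pd.DataFrame:
    """Per-motif two-sided rank-sum comparison of replicate counts.

    Wilcoxon–Mann–Whitney on the replicate motif counts of the two
    groups; the exact null distribution is used when the data are free
    of ties.  Returns unadjusted p-values alongside Holm-adjusted ones,
    indexed by motif.
    """
    censuses_a, censuses_b = list(censuses_a), list(censuses_b)
    if len(censuses_a) < 3 or len(censuses_b) < 3:
        raise ValueError("too few replicates: need at least 3 per group")
    p_values = []
    for motif in MOTIFS:
        x = np.array([c.counts[motif] for c in censuses_a], dtype=float)
        y = np.array([c.counts[motif] for c in censuses_b], dtype=float)
        combined = np.concatenate([x, y])
        if np.all(combined == combined[0]):
            p_values.append(1.0)
            continue
        has_ties = len(np.unique(combined)) < len(combined)
        method = "asymptotic" if has_ties else "exact"
        p = stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
        p_values.append(float(p))
    p_values = np.array(p_values)
    return pd.DataFrame(
        {"p_value": p_values, "p_holm": _holm(p_values)}, index=list(MOTIFS)
    )
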