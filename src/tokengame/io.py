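"""Reading and writing configs, contest histories, graphs and censuses.

Edge lists are TSV (ids may contain commas in empirical data); graphs go
through GraphML with token counts as node attributes; configs are JSON
or YAML keyed by the :class:`~tokengame.token_game.GameConfig` fields.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional, Tuple, Union

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .dominance import DominanceGraph
from .token_game import GameConfig, GameResult
from .triads import TriadCensus

__all__ = [
    "load_config",
    "save_config",
    "write_history_tsv",
    "write_tokens_csv",
    "write_graphml",
    "read_graphml",
    "read_edge_list_tsv",
    "write_census_csv",
]

PathLike = Union[str, Path]


def load_config(path: PathLike) -> GameConfig:
    """Load a game configuration from a JSON or YAML file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must hold a mapping")
    data = {k: v for k, v in data.items() if v is not None}
    return GameConfig.from_dict(data)


def save_config(config: GameConfig, path: PathLike) -> None:
    path = Path(path)
    data = config.to_dict()
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2) + "\n")


def write_history_tsv(result: GameResult, path: PathLike) -> None:
    """Contest history: season, contest, first, second, outcome, tokens after."""
    result.history_frame().to_csv(path, sep="\t", index=False)


def write_tokens_csv(result: GameResult, path: PathLike) -> None:
    """Per-season token counts, one row per competitor and season."""
    rows = []
    for season, token_vec in enumerate(result.season_tokens, start=1):
        for node, tokens in enumerate(token_vec):
            rows.append({"season": season, "competitor": node, "tokens": int(tokens)})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_graphml(
    graph: DominanceGraph,
    path: PathLike,
    tokens: Optional[Iterable[int]] = None,
) -> None:
    """Write the directed dominance graph, optionally with token attributes."""
    g = graph.to_directed()
    if tokens is not None:
        token_map = {node: int(t) for node, t in zip(graph.nodes, tokens)}
        nx.set_node_attributes(g, token_map, "tokens")
    nx.write_graphml(g, str(path))


def read_graphml(path: PathLike) -> DominanceGraph:
    """Read a directed GraphML file back into a dominance graph."""
    g = nx.read_graphml(str(path))
    if not g.is_directed():
        raise ValueError(f"{path} does not hold a directed graph")
    return DominanceGraph.from_edges(g.edges(), nodes=g.nodes())


def read_edge_list_tsv(path: PathLike) -> Tuple[list, list]:
    """Read a winner/loser TSV edge list, validating the dominance relation.

    The file needs columns ``winner`` and ``loser`` (extra columns are
    ignored).  Self-loops and mutual edges are rejected with the
    offending pair named.  Returns ``(nodes, edges)``.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"winner", "loser"} - set(frame.columns)
    if missing:
        raise ValueError(f"edge list {path} lacks columns: {sorted(missing)}")
    edges = []
    seen = set()
    for winner, loser in frame[["winner", "loser"]].itertuples(index=False):
        if winner == loser:
            raise ValueError(f"self-dominance on {winner!r}")
        if (loser, winner) in seen:
            raise ValueError(
                f"mutual dominance between {winner!r} and {loser!r}"
            )
        seen.add((winner, loser))
        edges.append((winner, loser))
    nodes = list(dict.fromkeys(n for e in edges for n in e))
    return nodes, edges


def write_census_csv(
    census: TriadCensus, path: PathLike, replicate: int = 0, season: int = 0
) -> None:
    pd.DataFrame(
        [
            {
                "replicate": replicate,
                "season": season,
                "dd": census.dd,
                "ds": census.ds,
                "pa": census.pa,
                "tr": census.tr,
                "cy": census.cy,
                "uncounted": census.n_uncounted,
            }
        ]
    ).to_csv(path, index=False)
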