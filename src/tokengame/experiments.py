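"""Replication harness: repeated games with per-season network metrics.

Runs a scenario across independent replicates (each with its own derived
seed), snapshots the dominance graph at requested seasons, and collects
the metrics used to characterize hierarchy formation: average shortest
undirected path, global reaching centrality, edge density, token spread,
and the triad motif census.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .dominance import average_shortest_path, global_reaching_centrality
from .token_game import GameConfig, Schedule, Variant, play_game
from .triads import TriadCensus, census, motif_pattern

__all__ = [
    "ExperimentSummary",
    "derive_replicate_seeds",
    "run_experiment",
    "scenario_presets",
    "token_histogram",
    "TOKEN_BIN_LABELS",
]

#: Token histogram categories: destitute, the gap value 2, poor, the
#: starting band, and the wealthy tail.
TOKEN_BINS: Tuple[Tuple[int, Optional[int]], ...] = (
    (0, 1),
    (2, 2),
    (3, 9),
    (10, 20),
    (21, None),
)
TOKEN_BIN_LABELS: Tuple[str, ...] = ("0-1", "2", "3-9", "10-20", ">20")


def derive_replicate_seeds(master_seed: int, n_replicates: int) -> List[int]:
    """Derive one distinct sub-seed per replicate from the master seed.

    The replicate seeds are consecutive 32-bit words of the NumPy
    seed-sequence stream keyed by the master seed, right-shifted one bit
    so they stay below 2**31.  The mapping is deterministic, so a summary
    can be reproduced from the master seed alone.
    """
    ss = np.random.SeedSequence(master_seed)
    words = ss.generate_state(n_replicates, dtype=np.uint32)
    return [int(w >> np.uint32(1)) for w in words]


@dataclass
class ExperimentSummary:
    """Per-replicate, per-season metrics of one repeated scenario."""

    config: GameConfig
    n_replicates: int
    seasons_evaluated: List[int]
    replicate_seeds: List[int]
    metrics: pd.DataFrame  # long: replicate, season, metric, value
    censuses: Dict[Tuple[int, int], TriadCensus]  # (replicate, season) -> census
    tokens: Dict[Tuple[int, int], np.ndarray]

    def censuses_at(self, season: int) -> List[TriadCensus]:
        return [
            self.censuses[(rep, season)] for rep in range(self.n_replicates)
        ]

    def motif_pattern_at(self, season: int) -> pd.DataFrame:
        return motif_pattern(self.censuses_at(season))

    def metric_values(self, metric: str, season: int) -> np.ndarray:
        frame = self.metrics
        sel = frame[(frame["metric"] == metric) & (frame["season"] == season)]
        return sel.sort_values("replicate")["value"].to_numpy()

    def aggregate(self) -> pd.DataFrame:
        """Mean/SD/quartiles/95% CI per metric and season, across replicates."""

        def _agg(values: pd.Series) -> pd.Series:
            v = values.to_numpy(dtype=float)
            return pd.Series(
                {
                    "mean": np.nanmean(v),
                    "sd": np.nanstd(v, ddof=1) if len(v) > 1 else 0.0,
                    "q25": np.nanpercentile(v, 25),
                    "q75": np.nanpercentile(v, 75),
                    "ci_low": np.nanpercentile(v, 2.5),
                    "ci_high": np.nanpercentile(v, 97.5),
                }
            )

        return (
            self.metrics.groupby(["season", "metric"])["value"]
            .apply(_agg)
            .unstack()
            .reset_index()
        )

    def census_frame(self) -> pd.DataFrame:
        """Censuses as a flat table: replicate, season, five motifs, uncounted."""
        rows = []
        for (rep, season), c in sorted(self.censuses.items()):
            rows.append(
                {
                    "replicate": rep,
                    "season": season,
                    "dd": c.dd,
                    "ds": c.ds,
                    "pa": c.pa,
                    "tr": c.tr,
                    "cy": c.cy,
                    "uncounted": c.n_uncounted,
                }
            )
        return pd.DataFrame(rows)


def run_experiment(
    config: GameConfig,
    n_replicates: int,
    seasons_evaluated: Optional[Sequence[int]] = None,
) -> ExperimentSummary:
    """Run ``n_replicates`` independent games and snapshot their metrics.

    Every replicate runs the same configuration under a distinct seed
    derived from ``config.seed``.  ``seasons_evaluated`` defaults to the
    final season only; requested seasons beyond ``config.n_seasons`` are
    an error.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if seasons_evaluated is None:
        seasons_evaluated = [config.n_seasons]
    seasons_evaluated = sorted(set(int(s) for s in seasons_evaluated))
    if seasons_evaluated[0] < 1 or seasons_evaluated[-1] > config.n_seasons:
        raise ValueError(
            f"seasons_evaluated must lie in [1, {config.n_seasons}]"
        )

    seeds = derive_replicate_seeds(config.seed, n_replicates)
    rows = []
    censuses: Dict[Tuple[int, int], TriadCensus] = {}
    tokens: Dict[Tuple[int, int], np.ndarray] = {}
    for rep, seed in enumerate(seeds):
        result = play_game(replace(config, seed=seed))
        for season in seasons_evaluated:
            graph = result.season_graphs[season - 1]
            token_vec = result.season_tokens[season - 1]
            tokens[(rep, season)] = token_vec
            censuses[(rep, season)] = census(graph)
            try:
                apl = average_shortest_path(graph)
            except ValueError:
                apl = float("nan")
            metric_values = {
                "avg_shortest_path": apl,
                "global_reaching_centrality": global_reaching_centrality(graph),
                "edge_density": graph.edge_density,
                "token_sd": float(np.std(token_vec, ddof=1)),
                "n_active": int((token_vec > 0).sum()),
            }
            for metric, value in metric_values.items():
                rows.append(
                    {
                        "replicate": rep,
                        "season": season,
                        "metric": metric,
                        "value": value,
                    }
                )

    return ExperimentSummary(
        config=config,
        n_replicates=n_replicates,
        seasons_evaluated=seasons_evaluated,
        replicate_seeds=seeds,
        metrics=pd.DataFrame(rows),
        censuses=censuses,
        tokens=tokens,
    )


def scenario_presets() -> Dict[str, GameConfig]:
    """The study scenarios, parameterized as in the published setups.

    All presets default to the null variant and 30 seasons; switch the
    variant with ``dataclasses.replace`` (or the CLI ``--variant`` flag).
    """
    return {
        "small12_allpairs": GameConfig(
            variant=Variant.NULL,
            n_competitors=12,
            n_seasons=30,
            schedule=Schedule.ALL_PAIRS,
        ),
        "grid4x4_spatial": GameConfig(
            variant=Variant.NULL,
            n_competitors=16,
            n_seasons=30,
            schedule=Schedule.SPATIAL,
            grid_rows=4,
            grid_cols=4,
            gompertz_b=15.0,
            gompertz_c=1.0,
        ),
        "grid20x20_spatial_c10": GameConfig(
            variant=Variant.NULL,
            n_competitors=400,
            n_seasons=30,
            schedule=Schedule.SPATIAL,
            grid_rows=20,
            grid_cols=20,
            gompertz_b=15.0,
            gompertz_c=1.0,
        ),
        "grid20x20_spatial_c15": GameConfig(
            variant=Variant.NULL,
            n_competitors=400,
            n_seasons=30,
            schedule=Schedule.SPATIAL,
            grid_rows=20,
            grid_cols=20,
            gompertz_b=15.0,
            gompertz_c=1.5,
        ),
    }


def token_histogram(
    tokens: Sequence[int], bin_edges: Optional[Sequence[float]] = None
):
    """Bin token counts into wealth categories.

    With no ``bin_edges`` the categories are {0-1, 2, 3-9, 10-20, >20},
    a partition of the non-negative integers; custom edges fall through
    to ``numpy.histogram``.  Returns ``(counts, labels)``.
    """
    values = np.asarray(tokens)
    if np.any(values < 0):
        raise ValueError("corrupt state: negative token count")
    if bin_edges is not None:
        counts, edges = np.histogram(values, bins=bin_edges)
        labels = [f"[{edges[k]:g},{edges[k+1]:g})" for k in range(len(counts))]
        labels[-1] = f"[{edges[-2]:g},{edges[-1]:g}]"
        return counts, labels
    counts = np.zeros(len(TOKEN_BINS), dtype=int)
    for k, (lo, hi) in enumerate(TOKEN_BINS):
        if hi is None:
            counts[k] = int((values >= lo).sum())
        else:
            counts[k] = int(((values >= lo) & (values <= hi)).sum())
    return counts, list(TOKEN_BIN_LABELS)
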