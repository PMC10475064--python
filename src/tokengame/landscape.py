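"""Jittered rectangular landscapes and the Gompertz contest scheduler.

Large groups do not fight all-pairs; contests happen between spatial
neighbours.  Competitors sit on a rectangular lattice with standard
spacing 1.0 +/- epsilon, and each unordered pair fights in a given season
with a probability that decays with distance following a reversed
Gompertz sigmoid ``p(x) = 1 - exp(-b * exp(-c * x))``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np

__all__ = [
    "Landscape",
    "NeighborSummary",
    "make_lattice",
    "gompertz_probability",
    "gompertz_half_distance",
    "season_pairs_spatial",
    "expected_neighbors",
]


def gompertz_probability(distance, b: float, c: float):
    """Contest probability at a given spatial distance.

    ``p(x) = 1 - exp(-b * exp(-c * x))``: a reversed double-exponential
    sigmoid, strictly decreasing in ``x``, close to 1 at distance zero
    and tending to 0 far away.  ``b`` sets the half-probability distance
    ``ln(b / ln 2) / c``; ``c`` sets the steepness of the drop.

    Accepts scalars or arrays; distances must be non-negative.
    """
    if b <= 0 or c <= 0:
        raise ValueError(f"invalid Gompertz parameters: b={b}, c={c} (must be > 0)")
    d = np.asarray(distance, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    p = 1.0 - np.exp(-b * np.exp(-c * d))
    return float(p) if np.isscalar(distance) else p


def gompertz_half_distance(b: float, c: float) -> float:
    """Distance at which the contest probability equals 1/2 exactly."""
    if b <= 0 or c <= 0:
        raise ValueError(f"invalid Gompertz parameters: b={b}, c={c} (must be > 0)")
    return float(np.log(b / np.log(2.0)) / c)


@dataclass
class Landscape:
    """A fixed arena: jittered lattice positions plus per-pair contest odds.

    Node ``r * cols + c`` sits near grid cell ``(r, c)``; ``pair_i`` /
    ``pair_j`` index all unordered pairs, with Euclidean ``distances``
    and Gompertz ``probabilities`` precomputed once at creation.
    """

    rows: int
    cols: int
    epsilon: float
    b: float
    c: float
    positions: np.ndarray  # (n, 2) coordinates (x, y)
    pair_i: np.ndarray
    pair_j: np.ndarray
    distances: np.ndarray
    probabilities: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.rows * self.cols

    def probability_matrix(self) -> np.ndarray:
        """Symmetric (n, n) matrix of pairwise contest probabilities."""
        n = self.n_nodes
        mat = np.zeros((n, n))
        mat[self.pair_i, self.pair_j] = self.probabilities
        mat[self.pair_j, self.pair_i] = self.probabilities
        return mat

    def to_frame(self):
        """Node table: id, grid row/col and jittered coordinates."""
        import pandas as pd

        n = self.n_nodes
        r, c = np.divmod(np.arange(n), self.cols)
        return pd.DataFrame(
            {
                "node": np.arange(n),
                "row": r,
                "col": c,
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
            }
        )


def make_lattice(
    rows: int,
    cols: int,
    epsilon: float,
    rng: Optional[np.random.Generator] = None,
    *,
    b: float = 15.0,
    c: float = 1.0,
) -> Landscape:
    """Build a jittered rows x cols lattice with unit standard spacing.

    The node at grid cell (r, c) gets position ``(c + u, r + v)`` with u, v
    independent uniform on ``[-epsilon/2, +epsilon/2]``, drawn once; the
    arena is fixed for the whole game.  All pairwise distances and
    Gompertz contest probabilities are precomputed.
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be positive")
    if epsilon < 0:
        raise ValueError(f"invalid jitter: epsilon={epsilon} (must be >= 0)")
    if b <= 0 or c <= 0:
        raise ValueError(f"invalid Gompertz parameters: b={b}, c={c} (must be > 0)")
    n = rows * cols
    r_idx, c_idx = np.divmod(np.arange(n), cols)
    positions = np.stack([c_idx.astype(float), r_idx.astype(float)], axis=1)
    if epsilon > 0:
        if rng is None:
            rng = np.random.default_rng()
        positions += rng.uniform(-epsilon / 2.0, epsilon / 2.0, size=(n, 2))
    pair_i, pair_j = np.triu_indices(n, k=1)
    distances = np.linalg.norm(positions[pair_i] - positions[pair_j], axis=1)
    probabilities = gompertz_probability(distances, b, c)
    return Landscape(
        rows=rows,
        cols=cols,
        epsilon=epsilon,
        b=b,
        c=c,
        positions=positions,
        pair_i=pair_i,
        pair_j=pair_j,
        distances=distances,
        probabilities=probabilities,
    )


def season_pairs_spatial(landscape: Landscape, rng: np.random.Generator) -> list:
    """Bernoulli-sample one season's contest pairs by distance.

    Each unordered pair is included independently with its Gompertz
    contest probability; the included pairs are returned in uniformly
    shuffled order.
    """
    mask = rng.random(landscape.probabilities.shape[0]) < landscape.probabilities
    idx = np.flatnonzero(mask)
    idx = idx[rng.permutation(idx.shape[0])]
    return [
        (int(landscape.pair_i[k]), int(landscape.pair_j[k])) for k in idx
    ]


class NeighborSummary(NamedTuple):
    values: np.ndarray  # per-node expected contests per season
    mean: float
    sd: float


def expected_neighbors(landscape: Landscape) -> NeighborSummary:
    """Per-node expected number of contests per season.

    For each node, the sum of contest probabilities to every other node:
    the size of its group of potential neighbouring competitors.  Returns
    the per-node vector plus mean and (sample) SD across nodes.
    """
    values = np.zeros(landscape.n_nodes)
    np.add.at(values, landscape.pair_i, landscape.probabilities)
    np.add.at(values, landscape.pair_j, landscape.probabilities)
    return NeighborSummary(
        values=values, mean=float(values.mean()), sd=float(values.std(ddof=1))
    )
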