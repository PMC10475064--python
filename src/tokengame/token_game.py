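"""Contest engine for the resource-token dominance game.

Each competitor holds an integer stock of tokens representing its resource
holding power (RHP).  In a pairwise contest both competitors put their
effective RHP worth of tokens into an urn; two tokens are drawn
independently, each with probability proportional to the owner's share.
Two tokens from the same owner decide the contest in that owner's favour;
a mixed draw is a draw.  Winners take one token from losers; a competitor
that reaches zero tokens drops out of all future contests.

The game variants differ only in what enters the urn:

``null``
    The starting stock, always.  Previous outcomes are ignored, so the
    odds between equal starters are fixed at 1/4 win, 1/4 lose, 1/2 draw.
``memory5``
    The starting stock plus the net outcome of the last ``memory_length``
    contests (win +1, loss -1, draw 0), floored at one token.
``winner_loser``
    The current token count: full state-dependent feedback, the
    winner-loser effect.
``keystone``
    As ``winner_loser``, but one designated competitor (id 0) starts with
    extra tokens -- an a-priori keystone individual.

Token accounting (winner +1, loser -1, dropout at zero) is identical in
every variant, so total tokens are conserved throughout a game.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace
from enum import Enum
from itertools import combinations
from typing import Deque, Optional, Sequence, Union

import numpy as np

__all__ = [
    "Variant",
    "Schedule",
    "Outcome",
    "ConfigError",
    "EliminatedCompetitorError",
    "GameConfig",
    "Competitor",
    "ContestResult",
    "GameResult",
    "effective_rhp",
    "contest_probabilities",
    "run_contest",
    "season_pairs_all",
    "play_game",
]


class Variant(str, Enum):
    """Feedback rule selecting what RHP enters the contest urn."""

    NULL = "null"
    MEMORY5 = "memory5"
    WINNER_LOSER = "winner_loser"
    KEYSTONE = "keystone"


class Schedule(str, Enum):
    """Season scheduling mode: every pair once, or distance-sampled pairs."""

    ALL_PAIRS = "all_pairs"
    SPATIAL = "spatial"


class Outcome(str, Enum):
    FIRST_WINS = "first_wins"
    SECOND_WINS = "second_wins"
    DRAW = "draw"


class ConfigError(ValueError):
    """A game configuration failed validation."""


class EliminatedCompetitorError(RuntimeError):
    """A competitor with zero tokens was asked to fight."""


@dataclass
class GameConfig:
    """Full parameterization of one simulation scenario.

    Parameters
    ----------
    variant
        Feedback rule, see :class:`Variant`.
    n_competitors
        Group size; at least 3 so that triads exist.
    n_seasons
        Number of seasons to play.  One all-pairs season comprises
        ``n(n-1)/2`` contests.
    initial_tokens
        Starting token stock ``T0`` per competitor.
    keystone_bonus
        Extra starting tokens for the designated keystone (competitor 0);
        only used by the ``keystone`` variant, where it must be positive.
    memory_length
        Number of most recent contests remembered by the ``memory5``
        variant.
    schedule
        ``all_pairs`` or ``spatial`` (closest-neighbour contests on a
        jittered lattice).
    gompertz_b, gompertz_c
        Parameters of the distance kernel ``p(x) = 1 - exp(-b e^(-c x))``
        used by the spatial schedule.  ``b`` shifts the half-probability
        distance, ``c`` sets the gradient.
    grid_rows, grid_cols
        Lattice shape for the spatial schedule; their product must equal
        ``n_competitors``.
    jitter_epsilon
        Positional jitter: lattice spacing is 1.0 +/- epsilon.
    seed
        Master seed; every stochastic draw of the game flows from it.
    """

    variant: Variant
    n_competitors: int
    n_seasons: int
    initial_tokens: int = 10
    keystone_bonus: int = 10
    memory_length: int = 5
    schedule: Schedule = Schedule.ALL_PAIRS
    gompertz_b: float = 15.0
    gompertz_c: float = 1.0
    grid_rows: Optional[int] = None
    grid_cols: Optional[int] = None
    jitter_epsilon: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        self.variant = Variant(self.variant)
        self.schedule = Schedule(self.schedule)
        self.validate()

    def validate(self) -> None:
        if self.n_competitors < 3:
            raise ConfigError("n_competitors must be >= 3 (triads must exist)")
        if self.n_seasons < 1:
            raise ConfigError("n_seasons must be a positive integer")
        if self.initial_tokens < 1:
            raise ConfigError("initial_tokens must be a positive integer")
        if self.memory_length < 1:
            raise ConfigError("memory_length must be a positive integer")
        if self.keystone_bonus < 0:
            raise ConfigError("keystone_bonus must be non-negative")
        if self.variant is Variant.KEYSTONE and self.keystone_bonus == 0:
            raise ConfigError("keystone variant requires keystone_bonus > 0")
        if self.gompertz_b <= 0 or self.gompertz_c <= 0:
            raise ConfigError("gompertz_b and gompertz_c must be positive")
        if self.jitter_epsilon < 0:
            raise ConfigError("jitter_epsilon must be non-negative")
        if self.schedule is Schedule.SPATIAL:
            if self.grid_rows is None or self.grid_cols is None:
                raise ConfigError("spatial schedule requires grid_rows and grid_cols")
            if self.grid_rows * self.grid_cols != self.n_competitors:
                raise ConfigError(
                    "grid_rows * grid_cols must equal n_competitors "
                    f"({self.grid_rows} * {self.grid_cols} != {self.n_competitors})"
                )

    def to_dict(self) -> dict:
        return {
            "variant": self.variant.value,
            "n_competitors": self.n_competitors,
            "n_seasons": self.n_seasons,
            "initial_tokens": self.initial_tokens,
            "keystone_bonus": self.keystone_bonus,
            "memory_length": self.memory_length,
            "schedule": self.schedule.value,
            "gompertz_b": self.gompertz_b,
            "gompertz_c": self.gompertz_c,
            "grid_rows": self.grid_rows,
            "grid_cols": self.grid_cols,
            "jitter_epsilon": self.jitter_epsilon,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "GameConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        missing = {"variant", "n_competitors", "n_seasons"} - set(data)
        if missing:
            raise ConfigError(f"missing required config fields: {sorted(missing)}")
        return cls(**data)


@dataclass
class Competitor:
    """A node in the game: token stock, contest memory, optional position."""

    id: int
    tokens: int
    base_rhp: int
    memory: Deque[int]
    position: Optional[tuple] = None

    @property
    def active(self) -> bool:
        return self.tokens > 0

    @classmethod
    def create(
        cls,
        id: int,
        tokens: int,
        memory_length: int,
        position: Optional[tuple] = None,
    ) -> "Competitor":
        return cls(
            id=id,
            tokens=tokens,
            base_rhp=tokens,
            memory=deque(maxlen=memory_length),
            position=position,
        )


@dataclass(frozen=True)
class ContestResult:
    """One pairwise contest outcome."""

    first: int
    second: int
    outcome: Outcome
    season_index: int
    contest_index: int

    def __post_init__(self) -> None:
        if self.first == self.second:
            raise ValueError("a competitor cannot contest itself")


def effective_rhp(competitor: Competitor, config: GameConfig) -> int:
    """Token count that enters the urn for this competitor, per variant.

    null: the starting stock; memory5: starting stock plus the net of the
    remembered outcomes, floored at 1; winner_loser / keystone: the
    current token count.
    """
    if not competitor.active:
        raise EliminatedCompetitorError(f"competitor {competitor.id} eliminated")
    if config.variant is Variant.NULL:
        return competitor.base_rhp
    if config.variant is Variant.MEMORY5:
        return max(1, competitor.base_rhp + sum(competitor.memory))
    # winner_loser and keystone: full state-dependent feedback
    return competitor.tokens


def contest_probabilities(rhp_a: int, rhp_b: int) -> tuple:
    """Win/lose/draw probabilities of the two-token urn draw.

    Two tokens are drawn independently, each belonging to A with
    probability ``q = rhp_a / (rhp_a + rhp_b)``.  Both from A: A wins;
    both from B: B wins; one each: draw.  Hence ``(q^2, (1-q)^2, 2q(1-q))``.
    Equal stocks give exactly (1/4, 1/4, 1/2).
    """
    if rhp_a < 1 or rhp_b < 1:
        raise ValueError(f"invalid RHP: ({rhp_a}, {rhp_b}); both must be >= 1")
    q = rhp_a / (rhp_a + rhp_b)
    return (q * q, (1.0 - q) * (1.0 - q), 2.0 * q * (1.0 - q))


def _apply_outcome(a: Competitor, b: Competitor, outcome: Outcome) -> None:
    if outcome is Outcome.DRAW:
        a.memory.append(0)
        b.memory.append(0)
        return
    winner, loser = (a, b) if outcome is Outcome.FIRST_WINS else (b, a)
    winner.tokens += 1
    loser.tokens -= 1
    winner.memory.append(+1)
    loser.memory.append(-1)


def run_contest(
    a: Competitor,
    b: Competitor,
    config: GameConfig,
    rng: np.random.Generator,
    season_index: int = 0,
    contest_index: int = 0,
) -> ContestResult:
    """Play one contest between two active competitors and update them.

    Tokens move one at a time from loser to winner; draws move nothing.
    Both memories record the outcome (+1/-1/0), evicting the oldest mark
    past capacity.  A loser reaching zero tokens is thereby eliminated.
    """
    p_a, p_b, _ = contest_probabilities(
        effective_rhp(a, config), effective_rhp(b, config)
    )
    u = rng.random()
    if u < p_a:
        outcome = Outcome.FIRST_WINS
    elif u < p_a + p_b:
        outcome = Outcome.SECOND_WINS
    else:
        outcome = Outcome.DRAW
    _apply_outcome(a, b, outcome)
    return ContestResult(
        first=a.id,
        second=b.id,
        outcome=outcome,
        season_index=season_index,
        contest_index=contest_index,
    )


def season_pairs_all(n: int, rng: np.random.Generator) -> list:
    """All n(n-1)/2 unordered pairs in uniformly shuffled order."""
    if n < 2:
        raise ValueError("too few competitors: need n >= 2")
    pairs = list(combinations(range(n), 2))
    order = rng.permutation(len(pairs))
    return [pairs[k] for k in order]


@dataclass
class GameResult:
    """Everything one game produced.

    ``season_graphs[s]`` and ``season_tokens[s]`` are snapshots taken at
    the end of season ``s+1``; ``history`` lists the contests actually
    played (pairs with an eliminated member are skipped, not recorded).
    """

    config: GameConfig
    competitors: list
    history: list
    token_trace: list  # (tokens_first_after, tokens_second_after) per contest
    season_graphs: list
    season_tokens: list
    landscape: object = None

    @property
    def final_tokens(self) -> np.ndarray:
        return self.season_tokens[-1]

    @property
    def final_graph(self):
        return self.season_graphs[-1]

    def history_frame(self):
        """Contest history as a DataFrame (TSV-exportable)."""
        import pandas as pd

        rows = [
            (
                r.season_index,
                r.contest_index,
                r.first,
                r.second,
                r.outcome.value,
                tf,
                ts,
            )
            for r, (tf, ts) in zip(self.history, self.token_trace)
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "season",
                "contest",
                "first",
                "second",
                "outcome",
                "tokens_first_after",
                "tokens_second_after",
            ],
        )


def play_game(config: GameConfig) -> GameResult:
    """Run a full game: ``n_seasons`` seasons under the configured schedule.

    Each season the scheduler emits its pairs (all pairs shuffled, or
    Bernoulli-sampled by the Gompertz distance kernel); pairs with an
    eliminated member are skipped.  The dominance graph (directed
    winner->loser, most recent decisive outcome per pair, draws clear the
    edge) and the token vector are snapshotted after every season.
    Identical seeds give identical histories.
    """
    from .dominance import DominanceGraph
    from .landscape import make_lattice, season_pairs_spatial

    config.validate()
    rng = np.random.default_rng(config.seed)

    landscape = None
    positions = [None] * config.n_competitors
    if config.schedule is Schedule.SPATIAL:
        landscape = make_lattice(
            config.grid_rows,
            config.grid_cols,
            config.jitter_epsilon,
            rng,
            b=config.gompertz_b,
            c=config.gompertz_c,
        )
        positions = [tuple(p) for p in landscape.positions]

    competitors = []
    for i in range(config.n_competitors):
        tokens = config.initial_tokens
        if config.variant is Variant.KEYSTONE and i == 0:
            tokens += config.keystone_bonus
        competitors.append(
            Competitor.create(i, tokens, config.memory_length, positions[i])
        )

    graph = DominanceGraph(range(config.n_competitors))
    history: list = []
    token_trace: list = []
    season_graphs: list = []
    season_tokens: list = []

    for season in range(1, config.n_seasons + 1):
        if config.schedule is Schedule.ALL_PAIRS:
            pairs = season_pairs_all(config.n_competitors, rng)
        else:
            pairs = season_pairs_spatial(landscape, rng)
        contest_index = 0
        for i, j in pairs:
            a, b = competitors[i], competitors[j]
            if not (a.active and b.active):
                continue
            result = run_contest(a, b, config, rng, season, contest_index)
            contest_index += 1
            history.append(result)
            token_trace.append((a.tokens, b.tokens))
            graph.update(result)
        season_graphs.append(graph.copy())
        season_tokens.append(
            np.array([c.tokens for c in competitors], dtype=np.int64)
        )

    return GameResult(
        config=config,
        competitors=competitors,
        history=history,
        token_trace=token_trace,
        season_graphs=season_graphs,
        season_tokens=season_tokens,
        landscape=landscape,
    )
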