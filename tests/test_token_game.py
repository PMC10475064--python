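"""Contest engine: urn odds, token transfer, memory, season loops."""

from collections import deque
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tokengame import (
    Competitor,
    ConfigError,
    EliminatedCompetitorError,
    GameConfig,
    Outcome,
    Schedule,
    Variant,
    contest_probabilities,
    effective_rhp,
    play_game,
    run_contest,
    season_pairs_all,
)


class ForcedRng:
    """Stub generator returning a fixed uniform draw, to force outcomes."""

    def __init__(self, value):
        self.value = value

    def random(self):
        return self.value


_next_id = iter(range(10_000))


def make_competitor(tokens=10, base=10, memory=(), memory_length=5):
    return Competitor(
        id=next(_next_id),
        tokens=tokens,
        base_rhp=base,
        memory=deque(memory, maxlen=memory_length),
    )


class TestEffectiveRhp:
    def test_null_ignores_history(self):
        config = GameConfig(variant=Variant.NULL, n_competitors=3, n_seasons=1)
        competitor = make_competitor(tokens=17, base=10, memory=[1, 1, 1])
        assert effective_rhp(competitor, config) == 10

    def test_memory5_sums_recent_outcomes(self):
        config = GameConfig(variant=Variant.MEMORY5, n_competitors=3, n_seasons=1)
        competitor = make_competitor(base=10, memory=[+1, +1, -1, 0, +1])
        assert effective_rhp(competitor, config) == 12

    def test_memory5_floored_at_one(self):
        config = GameConfig(
            variant=Variant.MEMORY5, n_competitors=3, n_seasons=1, initial_tokens=2
        )
        competitor = make_competitor(tokens=1, base=2, memory=[-1, -1, -1, -1, -1])
        assert effective_rhp(competitor, config) == 1

    @pytest.mark.parametrize("variant", [Variant.WINNER_LOSER, Variant.KEYSTONE])
    def test_feedback_variants_use_current_tokens(self, variant):
        config = GameConfig(variant=variant, n_competitors=3, n_seasons=1)
        assert effective_rhp(make_competitor(tokens=17), config) == 17

    def test_eliminated_competitor_rejected(self):
        config = GameConfig(variant=Variant.NULL, n_competitors=3, n_seasons=1)
        with pytest.raises(EliminatedCompetitorError, match="eliminated"):
            effective_rhp(make_competitor(tokens=0), config)


class TestContestProbabilities:
    @pytest.mark.parametrize(
        "rhp_a,rhp_b,expected",
        [
            (10, 10, (0.25, 0.25, 0.5)),
            (3, 1, (0.5625, 0.0625, 0.375)),
            (1, 3, (0.0625, 0.5625, 0.375)),
        ],
    )
    def test_examples(self, rhp_a, rhp_b, expected):
        assert contest_probabilities(rhp_a, rhp_b) == pytest.approx(
            expected, abs=1e-15
        )

    @pytest.mark.parametrize("pair", [(0, 5), (5, 0), (-1, 3)])
    def test_invalid_rhp_rejected(self, pair):
        with pytest.raises(ValueError, match="invalid RHP"):
            contest_probabilities(*pair)

    @given(
        rhp_a=st.integers(min_value=1, max_value=10_000),
        rhp_b=st.integers(min_value=1, max_value=10_000),
    )
    def test_distribution_is_proper(self, rhp_a, rhp_b):
        p_a, p_b, p_draw = contest_probabilities(rhp_a, rhp_b)
        assert all(0.0 <= p <= 1.0 for p in (p_a, p_b, p_draw))
        assert p_a + p_b + p_draw == pytest.approx(1.0, abs=1e-12)

    @given(
        rhp_b=st.integers(min_value=1, max_value=500),
        rhp_a=st.integers(min_value=1, max_value=499),
    )
    def test_win_probability_increases_with_rhp(self, rhp_a, rhp_b):
        lower = contest_probabilities(rhp_a, rhp_b)[0]
        higher = contest_probabilities(rhp_a + 1, rhp_b)[0]
        assert higher > lower


class TestRunContest:
    def config(self, variant=Variant.WINNER_LOSER):
        return GameConfig(variant=variant, n_competitors=3, n_seasons=1)

    def test_decisive_outcome_transfers_one_token(self):
        a, b = make_competitor(10), make_competitor(10)
        result = run_contest(a, b, self.config(), ForcedRng(0.0))
        assert result.outcome is Outcome.FIRST_WINS
        assert (a.tokens, b.tokens) == (11, 9)
        assert a.tokens + b.tokens == 20
        assert list(a.memory) == [1] and list(b.memory) == [-1]

    def test_losing_last_token_eliminates(self):
        a, b = make_competitor(1), make_competitor(10)
        result = run_contest(a, b, self.config(), ForcedRng(0.5))
        assert result.outcome is Outcome.SECOND_WINS
        assert a.tokens == 0 and not a.active

    def test_draw_changes_nothing_but_memory(self):
        a, b = make_competitor(7), make_competitor(13)
        p_a, p_b, _ = contest_probabilities(7, 13)
        result = run_contest(a, b, self.config(), ForcedRng(p_a + p_b + 1e-9))
        assert result.outcome is Outcome.DRAW
        assert (a.tokens, b.tokens) == (7, 13)
        assert list(a.memory) == [0] and list(b.memory) == [0]

    def test_memory_evicts_oldest_past_capacity(self):
        a = make_competitor(memory=[1, 1, 1, 1, 1])
        b = make_competitor()
        run_contest(a, b, self.config(), ForcedRng(0.0))
        assert list(a.memory) == [1, 1, 1, 1, 1]
        assert len(a.memory) == 5

    def test_inactive_participant_rejected(self):
        a, b = make_competitor(0), make_competitor(10)
        with pytest.raises(EliminatedCompetitorError):
            run_contest(a, b, self.config(), ForcedRng(0.5))


class TestSeasonPairsAll:
    @pytest.mark.parametrize("n,expected", [(3, 3), (12, 66), (20, 190)])
    def test_pair_count_and_uniqueness(self, n, expected, rng):
        pairs = season_pairs_all(n, rng)
        assert len(pairs) == expected
        assert len(set(map(frozenset, pairs))) == expected

    def test_too_few_competitors(self, rng):
        with pytest.raises(ValueError, match="too few"):
            season_pairs_all(1, rng)


class TestGameConfig:
    def test_keystone_requires_bonus(self):
        with pytest.raises(ConfigError, match="keystone_bonus"):
            GameConfig(
                variant=Variant.KEYSTONE,
                n_competitors=12,
                n_seasons=1,
                keystone_bonus=0,
            )

    def test_spatial_requires_matching_grid(self):
        with pytest.raises(ConfigError, match="grid"):
            GameConfig(
                variant=Variant.NULL,
                n_competitors=12,
                n_seasons=1,
                schedule=Schedule.SPATIAL,
                grid_rows=4,
                grid_cols=4,
            )

    def test_from_dict_names_missing_field(self):
        with pytest.raises(ConfigError, match="n_competitors"):
            GameConfig.from_dict({"variant": "null", "n_seasons": 1})


class TestPlayGame:
    def test_first_season_has_all_contests(self, null_config):
        result = play_game(replace(null_config, n_seasons=1))
        assert len(result.history) == 66

    def test_identical_seed_identical_history(self, variant_configs):
        for config in variant_configs.values():
            first = play_game(config)
            second = play_game(config)
            assert first.history == second.history
            assert all(
                np.array_equal(x, y)
                for x, y in zip(first.season_tokens, second.season_tokens)
            )

    def test_tokens_conserved_every_season_every_variant(self, variant_configs):
        for variant, config in variant_configs.items():
            result = play_game(replace(config, n_seasons=10))
            total = config.initial_tokens * config.n_competitors
            if variant is Variant.KEYSTONE:
                total += config.keystone_bonus
            for tokens in result.season_tokens:
                assert tokens.sum() == total
                assert (tokens >= 0).all()

    def test_keystone_starts_with_bonus(self, variant_configs):
        result = play_game(variant_configs[Variant.KEYSTONE])
        assert result.competitors[0].base_rhp == 20
        assert all(c.base_rhp == 10 for c in result.competitors[1:])

    def test_null_outcome_frequencies_match_quarter_half(self):
        # stateless odds in the null variant: aggregate over whole games
        wins = draws = total = 0
        for seed in range(12):
            config = GameConfig(
                variant=Variant.NULL, n_competitors=12, n_seasons=20, seed=seed
            )
            for contest in play_game(config).history:
                total += 1
                wins += contest.outcome is Outcome.FIRST_WINS
                draws += contest.outcome is Outcome.DRAW
        assert total >= 10_000
        se_win = np.sqrt(0.25 * 0.75 / total)
        se_draw = np.sqrt(0.5 * 0.5 / total)
        assert abs(wins / total - 0.25) < 3 * se_win
        assert abs(draws / total - 0.5) < 3 * se_draw

    def test_memory5_rhp_matches_contest_log(self):
        config = GameConfig(
            variant=Variant.MEMORY5, n_competitors=8, n_seasons=6, seed=5
        )
        result = play_game(config)
        marks = {i: [] for i in range(8)}
        for contest in result.history:
            if contest.outcome is Outcome.DRAW:
                marks[contest.first].append(0)
                marks[contest.second].append(0)
            elif contest.outcome is Outcome.FIRST_WINS:
                marks[contest.first].append(+1)
                marks[contest.second].append(-1)
            else:
                marks[contest.first].append(-1)
                marks[contest.second].append(+1)
        for competitor in result.competitors:
            if not competitor.active:
                continue
            expected = max(
                1, competitor.base_rhp + sum(marks[competitor.id][-5:])
            )
            assert effective_rhp(competitor, config) == expected

    def test_winner_loser_spreads_tokens_more_than_null(self, variant_configs):
        def mean_final_sd(config):
            sds = []
            for seed in range(10):
                result = play_game(replace(config, seed=seed))
                sds.append(np.std(result.final_tokens, ddof=1))
            return np.mean(sds)

        assert mean_final_sd(variant_configs[Variant.WINNER_LOSER]) > mean_final_sd(
            variant_configs[Variant.NULL]
        )

    def test_spread_nondecreasing_across_seasons_in_expectation(self, null_config):
        config = replace(null_config, variant=Variant.WINNER_LOSER, n_seasons=30)
        deviations = np.zeros((10, 30))
        for seed in range(10):
            result = play_game(replace(config, seed=seed))
            for s, tokens in enumerate(result.season_tokens):
                deviations[seed, s] = np.abs(tokens - 10).mean()
        means = deviations.mean(axis=0)
        # replicate-mean absolute deviation from T0 grows with season;
        # the finite-sample estimate may dip within sampling noise
        assert (np.diff(means) >= -0.1).all()
        assert means[-1] > means[0]

    def test_history_frame_tracks_tokens(self, null_config):
        result = play_game(replace(null_config, n_seasons=2))
        frame = result.history_frame()
        assert list(frame.columns) == [
            "season",
            "contest",
            "first",
            "second",
            "outcome",
            "tokens_first_after",
            "tokens_second_after",
        ]
        assert len(frame) == len(result.history)
        assert (frame["tokens_first_after"] >= 0).all()
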