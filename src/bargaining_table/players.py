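"""Synthetic player populations and choice behavior.

No human dataset ships with this package, so tournaments and model
training run against simulated players.  Two ingredients define the
synthetic world:

* a population of SVO angles, drawn from a two-component normal mixture
  (individualistic and prosocial components straddling the conventional
  22.5 deg boundary), split into a blue (P1) and an orange (P2) cohort;

* a logistic ground-truth choice model giving each player's probability
  of implementing the focal solution on a board.  The probability rises
  with the player's SVO angle and with the board's focal prominence, and
  shifts with the player's expected revenue share and strategic position.
  When a player does not play focally they assign each disc to their own
  square independently with probability ``self_bias``; the default of 0.5
  models non-focal play as uncoordinated ad-hoc allocation rather than
  perfect greed.  Setting ``self_bias = 1`` recovers strictly greedy
  non-focal play.

All draws are reproducible from explicit integer seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FeatureVector, PlayerProfile, extract_features
from .game import (
    AssignmentVector,
    BoardConfig,
    GameBoard,
    Player,
    closeness_solution,
    greedy_solution,
    random_board,
)

__all__ = [
    "SvoMixtureComponent",
    "PopulationConfig",
    "ChoiceModelConfig",
    "sample_population",
    "simulate_choice",
    "generate_training_dataset",
]


@dataclass(frozen=True)
class SvoMixtureComponent:
    mean: float
    sd: float
    weight: float


@dataclass(frozen=True)
class PopulationConfig:
    """SVO population: mixture shape, cohort sizes and seed.

    Defaults emulate the evaluation cohort: 93 players, 41 blue and 52
    orange, with equal-weight individualistic (5 deg +/- 8) and prosocial
    (32 deg +/- 6) components.
    """

    n_players: int = 93
    side_split: tuple[int, int] = (41, 52)
    components: tuple[SvoMixtureComponent, ...] = (
        SvoMixtureComponent(mean=5.0, sd=8.0, weight=0.5),
        SvoMixtureComponent(mean=32.0, sd=6.0, weight=0.5),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_players < 1:
            raise ValueError("n_players must be >= 1")
        if sum(self.side_split) != self.n_players:
            raise ValueError("side_split must sum to n_players")
        if not math.isclose(sum(c.weight for c in self.components), 1.0):
            raise ValueError("mixture weights must sum to 1")


@dataclass(frozen=True)
class ChoiceModelConfig:
    """Logistic ground truth for P(focal | features).

    logit P = b0 + b_svo * (svo - 22.5) + b_fpp * (fpp - fpp_center)
            + b_pos * position + b_erp * (erp - 0.5)

    ``b_svo > 0`` makes focal play rise with prosociality; ``b_fpp > 0``
    makes salient boards pull everyone toward the focal solution, so that
    board structure matters alongside personality.  ``self_bias`` governs
    non-focal play (see module docstring).
    """

    b0: float = -0.3
    b_svo: float = 0.05
    b_fpp: float = 1.8
    b_pos: float = 1.0
    b_erp: float = 3.0
    svo_center: float = 22.5
    fpp_center: float = 2.0
    self_bias: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.self_bias <= 1.0:
            raise ValueError("self_bias must lie in [0, 1]")

    def p_focal(self, features: FeatureVector) -> float:
        """Ground-truth probability of focal play for one instance."""
        logit = (
            self.b0
            + self.b_svo * (features.x6_svo_angle - self.svo_center)
            + self.b_fpp * (features.x1_fpp - self.fpp_center)
            + self.b_pos * features.x3_position
            + self.b_erp * (features.x2_erp - 0.5)
        )
        return 1.0 / (1.0 + math.exp(-logit))


def sample_population(config: PopulationConfig | None = None) -> list[PlayerProfile]:
    """Draw a seeded population of player profiles.

    The first ``side_split[0]`` players are blue (P1), the rest orange
    (P2); SVO angles are mixture draws clipped to the admissible
    [-90, 90] range.
    """
    config = config or PopulationConfig()
    rng = np.random.default_rng(config.seed)
    weights = np.array([c.weight for c in config.components])
    comp = rng.choice(len(config.components), size=config.n_players, p=weights)
    means = np.array([c.mean for c in config.components])[comp]
    sds = np.array([c.sd for c in config.components])[comp]
    angles = np.clip(rng.normal(means, sds), -90.0, 90.0)
    profiles = []
    for i, angle in enumerate(angles):
        side = Player.P1 if i < config.side_split[0] else Player.P2
        profiles.append(
            PlayerProfile(player_id=f"player_{i:03d}", svo_angle=float(angle), side=side)
        )
    return profiles


def simulate_choice(
    profile: PlayerProfile,
    board: GameBoard,
    choice_model: ChoiceModelConfig,
    rng: int | np.random.Generator,
) -> tuple[int, AssignmentVector]:
    """Simulate one player's decision on one board.

    Draws y ~ Bernoulli(P(focal | features)); a focal player (y = 1) plays
    the closeness solution, a non-focal player assigns each disc to their
    own square independently with probability ``self_bias``.
    """
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    p = choice_model.p_focal(extract_features(board, profile))
    y = int(gen.uniform() < p)
    if y == 1:
        return y, closeness_solution(board)
    if choice_model.self_bias >= 1.0:
        return y, greedy_solution(board, profile.side)
    keep = gen.uniform(size=board.n_discs) < choice_model.self_bias
    choices = tuple(profile.side if k else profile.side.other for k in keep)
    return y, AssignmentVector(choices)


def generate_training_dataset(
    n_players: int = 38,
    n_boards: int = 10,
    population: PopulationConfig | None = None,
    choice_model: ChoiceModelConfig | None = None,
    board_config: BoardConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate the model-construction study: each synthetic player plays
    ``n_boards`` fresh random boards.

    Returns a DataFrame with one row per (player, board): feature columns
    x1..x6, the binary label ``y`` and provenance ids (380 rows under the
    defaults: 38 players x 10 boards).
    """
    choice_model = choice_model or ChoiceModelConfig()
    board_config = board_config or BoardConfig()
    if population is None:
        n1 = n_players // 2
        population = PopulationConfig(
            n_players=n_players, side_split=(n1, n_players - n1), seed=seed
        )
    profiles = sample_population(population)
    if len(profiles) != n_players:
        raise ValueError("population size must equal n_players")
    rng = np.random.default_rng(seed)
    rows = []
    for profile in profiles:
        for j in range(n_boards):
            board = random_board(rng, board_config)
            fv = extract_features(board, profile)
            y, _ = simulate_choice(profile, board, choice_model, rng)
            rows.append(
                {
                    **fv.as_dict(),
                    "y": y,
                    "player_id": profile.player_id,
                    "board_id": f"{profile.player_id}_b{j:02d}",
                }
            )
    return pd.DataFrame(rows)
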