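"""Predictors of focal-point play for one (player, board) instance.

Six features feed the behavioral model:

* ``x1_fpp`` — focal point prominence: per disc, the ratio of the larger to
  the smaller of its Euclidean distances to the two squares (>= 1; 1 means
  the cell offers no focality, 7 is the maximum on the default geometry);
  aggregated over a board's discs by mean (default) or max.
* ``x2_erp`` — expected revenue proportion: the player's fraction of total
  points if both sides play the closeness rule, in [0, 1].
* ``x3_position`` — strategic position: +1 dominant, 0 equal, -1 weak.
* ``x4_total_points`` — total disc value on the board.
* ``x5_n_discs`` — number of discs.
* ``x6_svo_angle`` — the player's social value orientation angle in degrees
  (> 22.5 deg is conventionally prosocial).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .errors import DegeneratePositionError, EmptyBoardError
from .game import (
    Disc,
    GameBoard,
    GridPosition,
    Player,
    euclidean_distance,
    focal_points,
    strategic_position_of,
)

__all__ = [
    "FeatureVector",
    "PlayerProfile",
    "FEATURE_NAMES",
    "fpp",
    "board_fpp",
    "erp",
    "strategic_position",
    "extract_features",
]

FEATURE_NAMES = ("x1_fpp", "x2_erp", "x3_position", "x4_total_points", "x5_n_discs", "x6_svo_angle")

FppAggregation = Literal["mean", "max"]


@dataclass(frozen=True)
class PlayerProfile:
    """A player identity: an opaque id, an SVO angle and a side."""

    player_id: str
    svo_angle: float
    side: Player

    def __post_init__(self) -> None:
        if not -90.0 <= float(self.svo_angle) <= 90.0:
            raise ValueError(f"svo_angle outside [-90, 90]: {self.svo_angle}")


@dataclass(frozen=True)
class FeatureVector:
    x1_fpp: float
    x2_erp: float
    x3_position: int
    x4_total_points: int
    x5_n_discs: int
    x6_svo_angle: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


def fpp(disc: Disc | GridPosition, r1: GridPosition, r2: GridPosition) -> float:
    """Focal point prominence of a single disc (or bare cell)."""
    pos = disc.position if isinstance(disc, Disc) else disc
    d1 = euclidean_distance(r1, pos)
    d2 = euclidean_distance(r2, pos)
    lo, hi = min(d1, d2), max(d1, d2)
    if lo == 0.0:
        raise DegeneratePositionError(f"disc at ({pos.x},{pos.y}) sits on a square")
    return hi / lo


def board_fpp(board: GameBoard, aggregation: FppAggregation = "mean") -> float:
    """Aggregate per-disc prominence into one board-level value.

    The prominence measure is defined per disc; a game-level predictor
    needs one number, so the per-disc values are combined by arithmetic
    mean (default, smooth) or max.  For a one-disc board both choices
    coincide with the disc's own value.
    """
    if board.n_discs == 0:
        raise EmptyBoardError("board_fpp needs at least one disc")
    values = [fpp(d, board.config.r1, board.config.r2) for d in board.discs]
    if aggregation == "mean":
        return sum(values) / len(values)
    if aggregation == "max":
        return max(values)
    raise ValueError(f"unknown aggregation {aggregation!r}")


def erp(board: GameBoard, side: Player) -> float:
    """Expected revenue proportion of ``side`` under the mutual focal play."""
    p1, p2 = focal_points(board)
    own = p1 if Player(side) is Player.P1 else p2
    return own / board.total_points


def strategic_position(board: GameBoard, side: Player) -> int:
    """+1 / 0 / -1 classification of the focal share against one half."""
    return strategic_position_of(board, side)


def extract_features(
    board: GameBoard,
    profile: PlayerProfile,
    fpp_aggregation: FppAggregation = "mean",
) -> FeatureVector:
    """Assemble the six predictors for one (player, board) instance."""
    return FeatureVector(
        x1_fpp=board_fpp(board, fpp_aggregation),
        x2_erp=erp(board, profile.side),
        x3_position=strategic_position(board, profile.side),
        x4_total_points=board.total_points,
        x5_n_discs=board.n_discs,
        x6_svo_angle=float(profile.svo_angle),
    )
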