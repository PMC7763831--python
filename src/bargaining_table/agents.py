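"""Agent policies for the Bargaining Table.

Four policies are implemented:

* cooperative — always plays the focal (closeness-rule) solution;
* greedy — always assigns every disc to itself;
* dichotomous — plays cooperatively against opponents whose SVO angle is
  strictly above a cutoff (22.5 deg by default, the conventional
  prosocial/individualistic boundary) and greedily otherwise;
* adaptive — predicts the opponent's probability of focal play (``P_FP``)
  with the behavioral model, draws X ~ U[0, 1] and plays the focal
  solution iff ``P_FP > X``, otherwise the greedy one.

The adaptive agent's long-run per-board payoff has the closed form
``E = P_FP * profit_focal + (1 - P_FP) * profit_greedy``, exposed here as
:func:`expected_profit`.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import NamedTuple

import numpy as np

from .errors import BargainingTableError
from .features import PlayerProfile, extract_features
from .game import AssignmentVector, GameBoard, Player, closeness_solution, greedy_solution
from .model import TrainedModel, predict_pfp

__all__ = [
    "PolicyKind",
    "AgentSpec",
    "AdaptiveDecision",
    "cooperative_act",
    "greedy_act",
    "dichotomous_act",
    "adaptive_act",
    "expected_profit",
    "DEFAULT_SVO_CUTOFF",
]

DEFAULT_SVO_CUTOFF = 22.5


class PolicyKind(str, Enum):
    COOPERATIVE = "cooperative"
    GREEDY = "greedy"
    DICHOTOMOUS = "dichotomous"
    ADAPTIVE = "adaptive"


@dataclass(frozen=True)
class AgentSpec:
    """Declarative description of an agent.

    ``model`` must be present exactly for the adaptive kind; ``svo_cutoff``
    only matters for the dichotomous kind.
    """

    kind: PolicyKind
    side: Player
    svo_cutoff: float = DEFAULT_SVO_CUTOFF
    model: TrainedModel | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if (self.kind is PolicyKind.ADAPTIVE) != (self.model is not None):
            raise ValueError("a behavioral model is required iff the agent is adaptive")


class AdaptiveDecision(NamedTuple):
    """Log record of one adaptive decision: the assignment played, the
    chosen pure policy, the model probability and the uniform draw."""

    assignment: AssignmentVector
    chosen: PolicyKind
    p_fp: float
    x: float


def cooperative_act(board: GameBoard) -> AssignmentVector:
    """The always-focal policy (identical to the closeness solution)."""
    return closeness_solution(board)


def greedy_act(board: GameBoard, side: Player) -> AssignmentVector:
    """The all-discs-to-self policy."""
    return greedy_solution(board, side)


def dichotomous_act(
    board: GameBoard,
    side: Player,
    opponent_svo: float,
    cutoff: float = DEFAULT_SVO_CUTOFF,
) -> AssignmentVector:
    """Cooperate iff the opponent's SVO is strictly above the cutoff.

    An opponent at exactly the cutoff is treated as individualistic
    (greedy branch): prosociality is the strict inequality.
    """
    if opponent_svo > cutoff:
        return cooperative_act(board)
    return greedy_act(board, side)


def adaptive_act(
    board: GameBoard,
    side: Player,
    opponent_profile: PlayerProfile,
    model: TrainedModel,
    rng: int | np.random.Generator,
) -> AdaptiveDecision:
    """One stochastic adaptive decision.

    Computes ``P_FP`` from the opponent's features on this board, draws
    X ~ U[0, 1], and plays the focal solution iff ``P_FP > X`` (the greedy
    solution on ``P_FP <= X``, ties included).
    """
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    p_fp = predict_pfp(model, extract_features(board, opponent_profile))
    x = float(gen.uniform())
    if p_fp > x:
        return AdaptiveDecision(cooperative_act(board), PolicyKind.COOPERATIVE, p_fp, x)
    return AdaptiveDecision(greedy_act(board, side), PolicyKind.GREEDY, p_fp, x)


def expected_profit(p_fp: float, profit_fp: float, profit_greedy: float) -> float:
    """Closed-form expected payoff of the stochastic policy mixture.

    ``p_fp * profit_fp + (1 - p_fp) * profit_greedy``; affine and monotone
    in ``p_fp`` with slope ``profit_fp - profit_greedy``.
    """
    if not 0.0 <= p_fp <= 1.0:
        raise BargainingTableError(f"p_fp must lie in [0, 1], got {p_fp}")
    return p_fp * profit_fp + (1.0 - p_fp) * profit_greedy
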