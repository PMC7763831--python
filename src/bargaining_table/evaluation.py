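"""Session and tournament runners.

A *session* is one agent playing the 10-board evaluation set against one
opponent; its accumulated payoff is the unit of comparison.  A
*tournament* replaces one side with an agent policy and runs a session
against every opponent on the other side, in both directions (agent as
blue against all orange players, then as orange against all blue
players).

Opponent behavior is frozen before any agent plays: each (opponent,
board) decision is simulated exactly once from the tournament seed and
shared by every policy, so payoff differences between policies are
attributable to the policies alone (a paired design).

For the adaptive agent the session additionally records the closed-form
expected total: the per-board mixture ``P_FP * profit_focal +
(1 - P_FP) * profit_greedy`` evaluated against the same frozen opponent
assignment.  Tournament summaries use that expectation as the adaptive
agent's score, which removes pure draw noise from the comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .agents import (
    AdaptiveDecision,
    AgentSpec,
    PolicyKind,
    adaptive_act,
    cooperative_act,
    dichotomous_act,
    expected_profit,
    greedy_act,
)
from .errors import PopulationError, SessionShapeError, SummaryError
from .features import PlayerProfile
from .game import AssignmentVector, GameBoard, Player, score_game
from .model import TrainedModel
from .players import ChoiceModelConfig, simulate_choice

__all__ = [
    "SessionResult",
    "TournamentSummary",
    "run_session",
    "freeze_opponent_play",
    "tournament",
    "tournament_table",
    "summarize",
]


@dataclass(frozen=True)
class SessionResult:
    policy: PolicyKind
    side: Player
    opponent_id: str
    payoffs: tuple[float, ...]
    total: float
    expected_total: float | None = None
    decisions: tuple[AdaptiveDecision, ...] | None = None

    @property
    def score(self) -> float:
        """The session score used in summaries: the closed-form expected
        total for the adaptive agent, the realized total otherwise."""
        return self.total if self.expected_total is None else self.expected_total


def run_session(
    agent: AgentSpec,
    opponent_assignments: Sequence[AssignmentVector],
    boards: Sequence[GameBoard],
    opponent_profile: PlayerProfile | None = None,
    rng: int | np.random.Generator | None = None,
) -> SessionResult:
    """Play one full session against a fixed (recorded) opponent.

    ``opponent_profile`` is required for the dichotomous and adaptive
    policies (they condition on the opponent); ``rng`` seeds the adaptive
    agent's uniform draws.
    """
    if len(opponent_assignments) != len(boards):
        raise SessionShapeError(
            f"{len(boards)} boards but {len(opponent_assignments)} opponent assignments"
        )
    if agent.kind in (PolicyKind.DICHOTOMOUS, PolicyKind.ADAPTIVE) and opponent_profile is None:
        raise ValueError(f"{agent.kind.value} agent needs the opponent profile")
    if agent.kind is PolicyKind.ADAPTIVE:
        if rng is None:
            rng = agent.seed if agent.seed is not None else 0
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)

    payoffs: list[float] = []
    expected: list[float] = []
    decisions: list[AdaptiveDecision] = []
    for board, opp_assignment in zip(boards, opponent_assignments):
        if agent.kind is PolicyKind.COOPERATIVE:
            own = cooperative_act(board)
        elif agent.kind is PolicyKind.GREEDY:
            own = greedy_act(board, agent.side)
        elif agent.kind is PolicyKind.DICHOTOMOUS:
            own = dichotomous_act(board, agent.side, opponent_profile.svo_angle, agent.svo_cutoff)
        else:
            decision = adaptive_act(board, agent.side, opponent_profile, agent.model, gen)
            own = decision.assignment
            decisions.append(decision)
            profit_fp = _payoff(board, cooperative_act(board), opp_assignment, agent.side)
            profit_greedy = _payoff(board, greedy_act(board, agent.side), opp_assignment, agent.side)
            expected.append(expected_profit(decision.p_fp, profit_fp, profit_greedy))
        payoffs.append(_payoff(board, own, opp_assignment, agent.side))

    return SessionResult(
        policy=agent.kind,
        side=agent.side,
        opponent_id=opponent_profile.player_id if opponent_profile else "fixed",
        payoffs=tuple(payoffs),
        total=float(sum(payoffs)),
        expected_total=float(sum(expected)) if agent.kind is PolicyKind.ADAPTIVE else None,
        decisions=tuple(decisions) if decisions else None,
    )


def _payoff(
    board: GameBoard, own: AssignmentVector, opp: AssignmentVector, side: Player
) -> float:
    if side is Player.P1:
        return score_game(board, own, opp).payoff_p1
    return score_game(board, opp, own).payoff_p2


def freeze_opponent_play(
    population: Sequence[PlayerProfile],
    boards: Sequence[GameBoard],
    choice_model: ChoiceModelConfig,
    seed: int = 0,
) -> dict[str, list[AssignmentVector]]:
    """Simulate every player's decision on every board exactly once.

    The per-player stream is derived from (seed, player index) only, so
    repeated calls — one per policy under comparison — reproduce identical
    opponent behavior.
    """
    frozen: dict[str, list[AssignmentVector]] = {}
    for i, profile in enumerate(population):
        gen = np.random.default_rng([seed, i])
        frozen[profile.player_id] = [
            simulate_choice(profile, board, choice_model, gen)[1] for board in boards
        ]
    return frozen


@dataclass(frozen=True)
class TournamentSummary:
    policy: PolicyKind
    sessions: Mapping[Player, tuple[SessionResult, ...]]

    def scores(self, side: Player) -> list[float]:
        return [s.score for s in self.sessions[side]]

    def stats(self, side: Player) -> dict[str, float]:
        return summarize(self.scores(side))


def tournament(
    policy: PolicyKind,
    population: Sequence[PlayerProfile],
    boards: Sequence[GameBoard],
    choice_model: ChoiceModelConfig | None = None,
    model: TrainedModel | None = None,
    seed: int = 0,
    frozen_play: Mapping[str, list[AssignmentVector]] | None = None,
) -> TournamentSummary:
    """Run the two-stage tournament for one policy.

    Stage one replaces the blue side: the agent plays every orange player.
    Stage two replaces the orange side against every blue player.  Opponent
    decisions come from ``frozen_play`` (or are frozen here from ``seed``),
    identical for every policy given the same seed.
    """
    choice_model = choice_model or ChoiceModelConfig()
    by_side = {
        Player.P1: [p for p in population if p.side is Player.P1],
        Player.P2: [p for p in population if p.side is Player.P2],
    }
    if not by_side[Player.P1] or not by_side[Player.P2]:
        raise PopulationError("tournament needs players on both sides")
    if frozen_play is None:
        frozen_play = freeze_opponent_play(population, boards, choice_model, seed)

    sessions: dict[Player, tuple[SessionResult, ...]] = {}
    for agent_side in (Player.P1, Player.P2):
        spec = AgentSpec(
            kind=policy,
            side=agent_side,
            model=model if policy is PolicyKind.ADAPTIVE else None,
        )
        results = []
        for k, opponent in enumerate(by_side[agent_side.other]):
            rng = np.random.default_rng([seed, 10_000 + k, 1 if agent_side is Player.P1 else 2])
            results.append(
                run_session(
                    spec,
                    frozen_play[opponent.player_id],
                    boards,
                    opponent_profile=opponent,
                    rng=rng,
                )
            )
        sessions[agent_side] = tuple(results)
    return TournamentSummary(policy=policy, sessions=sessions)


def tournament_table(summaries: Sequence[TournamentSummary]) -> pd.DataFrame:
    """Long-format results: one row per (policy, replaced side, opponent)."""
    rows = []
    for summary in summaries:
        for side, sessions in summary.sessions.items():
            for s in sessions:
                rows.append(
                    {
                        "policy": summary.policy.value,
                        "side_replaced": side.value,
                        "opponent_id": s.opponent_id,
                        "total": s.total,
                        "expected_total": s.expected_total,
                        "score": s.score,
                    }
                )
    return pd.DataFrame(rows)


def summarize(totals: Sequence[float]) -> dict[str, float]:
    """Five-number summary plus the mean of a payoff distribution."""
    if len(totals) == 0:
        raise SummaryError("cannot summarize an empty collection")
    arr = np.asarray(totals, dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return {
        "min": float(arr.min()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": float(arr.max()),
        "mean": float(arr.mean()),
    }
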