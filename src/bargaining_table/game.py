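"""Core of the Bargaining Table game.

The Bargaining Table is a two-player divergent-interest tacit coordination
game played on a 9 x 9 grid.  Each player owns one square; between one and
eight discs, each worth 1-5 points, are scattered over the remaining cells.
Both players silently assign *every* disc to one of the two squares.  A disc
pays its value to a player only when both assignments agree on that player;
on a disagreement both players are fined a fixed fraction (20 % by default)
of the disc's value.

The canonical cooperative reference solution is the *closeness rule*: give
each disc to the strictly nearer square.  It is the game's focal
(Schelling) point.  The greedy reference solution assigns every disc to the
acting player.

This module holds the board data model, legality checks, payoff scoring,
the two reference solutions, a random-board generator, and a constrained
generator for the 10-board evaluation set used in agent tournaments.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    AssignmentShapeError,
    ConstraintInfeasibleError,
    FocalTieError,
)

__all__ = [
    "Player",
    "GridPosition",
    "Disc",
    "BoardConfig",
    "GameBoard",
    "AssignmentVector",
    "JointOutcome",
    "euclidean_distance",
    "score_game",
    "closeness_solution",
    "greedy_solution",
    "focal_points",
    "strategic_position_of",
    "random_board",
    "generate_evaluation_set",
    "mirror_board",
    "legal_cells",
    "board_to_dict",
    "board_from_dict",
    "save_board_set",
    "load_board_set",
]


class Player(str, Enum):
    """One of the two sides: ``P1`` is the blue player, ``P2`` the orange."""

    P1 = "P1"
    P2 = "P2"

    @property
    def other(self) -> "Player":
        return Player.P2 if self is Player.P1 else Player.P1


@dataclass(frozen=True, order=True)
class GridPosition:
    """A 1-based (column, row) cell on the board."""

    x: int
    y: int

    def __post_init__(self) -> None:
        if not (isinstance(self.x, (int, np.integer)) and isinstance(self.y, (int, np.integer))):
            raise TypeError("grid coordinates must be integers")
        if self.x < 1 or self.y < 1:
            raise ValueError(f"grid coordinates must be >= 1, got {(self.x, self.y)}")


@dataclass(frozen=True)
class Disc:
    """A valued disc sitting on a grid cell."""

    position: GridPosition
    value: int

    def __post_init__(self) -> None:
        if not 1 <= int(self.value) <= 5:
            raise ValueError(f"disc value must be in 1..5, got {self.value}")


@dataclass(frozen=True)
class BoardConfig:
    """Geometry and payoff parameters shared by a set of boards.

    The default square placement ``r1=(2,5)``, ``r2=(8,5)`` spans the middle
    row of the 9 x 9 grid; with it the focal-point-prominence ratio over
    legal cells covers exactly the range [1, 7].
    """

    grid_size: int = 9
    r1: GridPosition = GridPosition(2, 5)
    r2: GridPosition = GridPosition(8, 5)
    penalty_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.grid_size < 2:
            raise ValueError("grid_size must be at least 2")
        if self.r1 == self.r2:
            raise ValueError("player squares must occupy distinct cells")
        for sq in (self.r1, self.r2):
            if sq.x > self.grid_size or sq.y > self.grid_size:
                raise ValueError("player square outside the grid")
        if not 0.0 <= self.penalty_fraction <= 1.0:
            raise ValueError("penalty_fraction must lie in [0, 1]")

    def square(self, player: Player) -> GridPosition:
        return self.r1 if player is Player.P1 else self.r2


@dataclass(frozen=True)
class GameBoard:
    """A single game instance: a configuration plus an ordered disc list."""

    config: BoardConfig
    discs: tuple[Disc, ...]

    def __post_init__(self) -> None:
        discs = tuple(self.discs)
        object.__setattr__(self, "discs", discs)
        if not 1 <= len(discs) <= 8:
            raise ValueError(f"a board carries 1..8 discs, got {len(discs)}")
        positions = [d.position for d in discs]
        if len(set(positions)) != len(positions):
            raise ValueError("disc positions must be distinct")
        for p in positions:
            if p.x > self.config.grid_size or p.y > self.config.grid_size:
                raise ValueError(f"disc at {p} outside the grid")
            if p in (self.config.r1, self.config.r2):
                raise ValueError(f"disc at {p} sits on a player square")

    @property
    def total_points(self) -> int:
        return sum(d.value for d in self.discs)

    @property
    def n_discs(self) -> int:
        return len(self.discs)


@dataclass(frozen=True)
class AssignmentVector:
    """One player's tacit allocation of every disc to one of the squares."""

    choices: tuple[Player, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "choices", tuple(Player(c) for c in self.choices))

    def __len__(self) -> int:
        return len(self.choices)

    def __iter__(self):
        return iter(self.choices)


@dataclass(frozen=True)
class JointOutcome:
    """Joint result of one scored game.

    ``agreed_value`` is the total value of discs both players assigned
    identically; ``disagreed_value`` is the rest.  The payoffs satisfy
    ``payoff_p1 + payoff_p2 = agreed_value - 2 * penalty * disagreed_value``.
    """

    payoff_p1: float
    payoff_p2: float
    agreed_value: int
    disagreed_value: int

    def payoff(self, player: Player) -> float:
        return self.payoff_p1 if player is Player.P1 else self.payoff_p2


def euclidean_distance(a: GridPosition, b: GridPosition) -> float:
    """Straight-line distance between two cells."""
    return math.hypot(a.x - b.x, a.y - b.y)


def score_game(board: GameBoard, a1: AssignmentVector, a2: AssignmentVector) -> JointOutcome:
    """Score one game given both players' assignment vectors.

    A disc assigned identically by both players pays its value to the
    agreed-upon player; a disc assigned differently fines *both* players
    ``penalty_fraction`` times its value.
    """
    if len(a1) != board.n_discs or len(a2) != board.n_discs:
        raise AssignmentShapeError(
            f"assignments of length {len(a1)}/{len(a2)} for a "
            f"{board.n_discs}-disc board"
        )
    pen = board.config.penalty_fraction
    p1 = p2 = 0.0
    agreed = disagreed = 0
    for disc, c1, c2 in zip(board.discs, a1, a2):
        if c1 == c2:
            agreed += disc.value
            if c1 is Player.P1:
                p1 += disc.value
            else:
                p2 += disc.value
        else:
            disagreed += disc.value
            p1 -= pen * disc.value
            p2 -= pen * disc.value
    return JointOutcome(payoff_p1=p1, payoff_p2=p2, agreed_value=agreed, disagreed_value=disagreed)


def closeness_solution(board: GameBoard) -> AssignmentVector:
    """The focal (closeness-rule) assignment: each disc to the strictly
    nearer square.

    Raises
    ------
    FocalTieError
        If any disc is equidistant from the two squares; the focal solution
        is undefined there and generators are expected to avoid such boards.
    """
    choices = []
    for disc in board.discs:
        d1 = euclidean_distance(board.config.r1, disc.position)
        d2 = euclidean_distance(board.config.r2, disc.position)
        # squared distances are integers, so exact comparison is safe
        s1 = (board.config.r1.x - disc.position.x) ** 2 + (board.config.r1.y - disc.position.y) ** 2
        s2 = (board.config.r2.x - disc.position.x) ** 2 + (board.config.r2.y - disc.position.y) ** 2
        if s1 == s2:
            raise FocalTieError(
                f"disc at ({disc.position.x},{disc.position.y}) is equidistant "
                f"from both squares (d={d1:.3f})"
            )
        choices.append(Player.P1 if s1 < s2 else Player.P2)
    return AssignmentVector(tuple(choices))


def greedy_solution(board: GameBoard, self_player: Player) -> AssignmentVector:
    """The all-to-self assignment for ``self_player``."""
    return AssignmentVector((Player(self_player),) * board.n_discs)


def focal_points(board: GameBoard) -> tuple[int, int]:
    """Per-player point totals when both sides play the closeness rule."""
    focal = closeness_solution(board)
    p1 = sum(d.value for d, c in zip(board.discs, focal) if c is Player.P1)
    return p1, board.total_points - p1


def strategic_position_of(board: GameBoard, side: Player) -> int:
    """Dominant (+1), equal (0) or weak (-1) focal position of ``side``.

    Compares twice the player's focal points against the board total in
    integer arithmetic, so the exact-half case is detected reliably.
    """
    p1, p2 = focal_points(board)
    own = p1 if Player(side) is Player.P1 else p2
    diff = 2 * own - board.total_points
    return 0 if diff == 0 else (1 if diff > 0 else -1)


# ---------------------------------------------------------------------------
# board generation
# ---------------------------------------------------------------------------


def legal_cells(config: BoardConfig) -> list[GridPosition]:
    """All cells a disc may occupy (everything but the two squares)."""
    return [
        GridPosition(x, y)
        for x in range(1, config.grid_size + 1)
        for y in range(1, config.grid_size + 1)
        if GridPosition(x, y) not in (config.r1, config.r2)
    ]


def _is_tie_cell(pos: GridPosition, config: BoardConfig) -> bool:
    s1 = (config.r1.x - pos.x) ** 2 + (config.r1.y - pos.y) ** 2
    s2 = (config.r2.x - pos.x) ** 2 + (config.r2.y - pos.y) ** 2
    return s1 == s2


def _as_rng(rng: int | np.random.Generator) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def random_board(rng: int | np.random.Generator, config: BoardConfig | None = None) -> GameBoard:
    """Draw a random legal board.

    Disc count ~ U{1..8}, disc values ~ U{1..5}, positions uniform without
    replacement over legal cells.  Position draws containing a cell
    equidistant from the two squares are rejected and redrawn, because the
    closeness rule is undefined there.
    """
    config = config or BoardConfig()
    gen = _as_rng(rng)
    cells = legal_cells(config)
    n = int(gen.integers(1, 9))
    values = gen.integers(1, 6, size=n)
    while True:
        idx = gen.choice(len(cells), size=n, replace=False)
        positions = [cells[i] for i in idx]
        if not any(_is_tie_cell(p, config) for p in positions):
            break
    discs = tuple(Disc(position=p, value=int(v)) for p, v in zip(positions, values))
    return GameBoard(config=config, discs=discs)


def _mirror_x(x: int, grid_size: int) -> int:
    return grid_size + 1 - x


def mirror_board(board: GameBoard) -> GameBoard:
    """Reflect a board across the grid's vertical midline.

    Requires the two squares to be mirror images of one another, in which
    case the reflection swaps the players' roles: P1's dominant board
    becomes P1's weak board and vice versa.
    """
    cfg = board.config
    if (_mirror_x(cfg.r1.x, cfg.grid_size), cfg.r1.y) != (cfg.r2.x, cfg.r2.y):
        raise ValueError("mirror_board requires mirror-symmetric square placement")
    discs = tuple(
        Disc(GridPosition(_mirror_x(d.position.x, cfg.grid_size), d.position.y), d.value)
        for d in board.discs
    )
    return GameBoard(config=cfg, discs=discs)


def _repair_totals(
    boards: list[GameBoard], gen: np.random.Generator, low: int, high: int
) -> list[GameBoard] | None:
    """Nudge disc values so the summed board totals land in [low, high],
    preserving P1 dominance of every board.  Returns None when stuck."""
    boards = list(boards)
    for _ in range(400):
        total = sum(b.total_points for b in boards)
        if low <= total <= high:
            return boards
        step = -1 if total > high else 1
        candidates = []
        for bi, board in enumerate(boards):
            focal = closeness_solution(board)
            for di, (disc, owner) in enumerate(zip(board.discs, focal)):
                if not 1 <= disc.value + step <= 5:
                    continue
                # decrementing opponent-side or incrementing own-side discs
                # can never break P1 dominance; others need a recheck
                p1, _ = focal_points(board)
                new_p1 = p1 + (step if owner is Player.P1 else 0)
                new_total = board.total_points + step
                if 2 * new_p1 > new_total:
                    candidates.append((bi, di))
        if not candidates:
            return None
        bi, di = candidates[int(gen.integers(len(candidates)))]
        board = boards[bi]
        new_discs = list(board.discs)
        old = new_discs[di]
        new_discs[di] = Disc(old.position, old.value + step)
        boards[bi] = GameBoard(config=board.config, discs=tuple(new_discs))
    return None


def _make_equal_board(
    gen: np.random.Generator, config: BoardConfig, points_per_player: int
) -> GameBoard:
    """Build a mirror-symmetric board worth ``points_per_player`` to each
    side under the closeness rule (strategic position 0 for both)."""
    if not 1 <= points_per_player <= 20:
        raise ValueError("points_per_player must be in 1..20")
    n_pairs = max(1, math.ceil(points_per_player / 5))
    base, extra = divmod(points_per_player, n_pairs)
    values = [base + (1 if i < extra else 0) for i in range(n_pairs)]
    # strictly-P1-side cells whose mirror image is also a legal disc cell
    left_cells = [
        c
        for c in legal_cells(config)
        if not _is_tie_cell(c, config)
        and euclidean_distance(c, config.r1) < euclidean_distance(c, config.r2)
        and GridPosition(_mirror_x(c.x, config.grid_size), c.y) not in (config.r1, config.r2)
    ]
    idx = gen.choice(len(left_cells), size=n_pairs, replace=False)
    discs = []
    for i, v in zip(idx, values):
        c = left_cells[int(i)]
        discs.append(Disc(c, v))
        discs.append(Disc(GridPosition(_mirror_x(c.x, config.grid_size), c.y), v))
    return GameBoard(config=config, discs=tuple(discs))


def generate_evaluation_set(
    rng: int | np.random.Generator,
    config: BoardConfig | None = None,
    target_total: int = 52,
    max_iter: int = 20_000,
) -> list[GameBoard]:
    """Generate the constrained 10-board evaluation set.

    The set satisfies, for each player, a strategic-position multiset of
    4 dominant / 4 weak / 2 equal boards, and gives each player exactly
    ``target_total`` points when both sides play the closeness rule on all
    ten boards.

    The search is a seeded rejection/repair procedure: random boards are
    drawn until four are dominant for P1; their disc values are nudged so
    the combined total leaves an attainable remainder; the four weak boards
    are the mirror images of the dominant ones (which swaps the players'
    roles and makes the focal totals automatically symmetric); and two
    mirror-symmetric equal boards absorb the remainder.

    Raises
    ------
    ConstraintInfeasibleError
        When ``max_iter`` candidate boards were drawn without satisfying
        the constraints; carries the best residual seen.
    """
    config = config or BoardConfig()
    gen = _as_rng(rng)
    # the mirror construction needs symmetric geometry
    if (_mirror_x(config.r1.x, config.grid_size), config.r1.y) != (config.r2.x, config.r2.y):
        raise ConstraintInfeasibleError(
            "evaluation-set search requires mirror-symmetric square placement"
        )
    draws = 0
    best_residual: float | None = None
    while True:
        dominant: list[GameBoard] = []
        while len(dominant) < 4:
            if draws >= max_iter:
                raise ConstraintInfeasibleError(
                    f"evaluation-set search budget ({max_iter} draws) exhausted",
                    best_residual=best_residual,
                )
            draws += 1
            cand = random_board(gen, config)
            if strategic_position_of(cand, Player.P1) == 1:
                dominant.append(cand)
        # remainder for the two equal boards must fit in [2, 40]
        repaired = _repair_totals(dominant, gen, target_total - 40, target_total - 2)
        if repaired is None:
            residual = abs(sum(b.total_points for b in dominant) - (target_total - 2))
            best_residual = residual if best_residual is None else min(best_residual, residual)
            continue
        dominant = repaired
        remainder = target_total - sum(b.total_points for b in dominant)
        e1, e2 = remainder // 2, remainder - remainder // 2
        equal_boards = [_make_equal_board(gen, config, e) for e in (e1, e2)]
        weak = [mirror_board(b) for b in dominant]
        boards = dominant + weak + equal_boards
        order = gen.permutation(len(boards))
        boards = [boards[i] for i in order]
        totals = evaluation_set_totals(boards)
        assert totals == (target_total, target_total)
        return boards


def evaluation_set_totals(boards: Sequence[GameBoard]) -> tuple[int, int]:
    """Each player's summed focal payoff over a board set when both sides
    play the closeness rule on every board (no penalties arise)."""
    p1 = p2 = 0
    for b in boards:
        f1, f2 = focal_points(b)
        p1 += f1
        p2 += f2
    return p1, p2


# ---------------------------------------------------------------------------
# JSON interchange
# ---------------------------------------------------------------------------


def board_to_dict(board: GameBoard) -> dict:
    cfg = board.config
    return {
        "grid_size": cfg.grid_size,
        "r1": [cfg.r1.x, cfg.r1.y],
        "r2": [cfg.r2.x, cfg.r2.y],
        "penalty_fraction": cfg.penalty_fraction,
        "discs": [{"x": d.position.x, "y": d.position.y, "value": d.value} for d in board.discs],
    }


def board_from_dict(data: dict) -> GameBoard:
    cfg = BoardConfig(
        grid_size=int(data.get("grid_size", 9)),
        r1=GridPosition(*map(int, data["r1"])),
        r2=GridPosition(*map(int, data["r2"])),
        penalty_fraction=float(data.get("penalty_fraction", 0.2)),
    )
    discs = tuple(
        Disc(GridPosition(int(d["x"]), int(d["y"])), int(d["value"])) for d in data["discs"]
    )
    return GameBoard(config=cfg, discs=discs)


def save_board_set(path: str | Path, boards: Iterable[GameBoard], seed: int | None = None) -> None:
    payload = {"seed": seed, "boards": [board_to_dict(b) for b in boards]}
    Path(path).write_text(json.dumps(payload, indent=2))


def load_board_set(path: str | Path) -> list[GameBoard]:
    payload = json.loads(Path(path).read_text())
    return [board_from_dict(b) for b in payload["boards"]]
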