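"""Board model, scoring rules, reference solutions and generators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bargaining_table import (
    AssignmentVector,
    BoardConfig,
    Disc,
    GameBoard,
    GridPosition,
    Player,
    closeness_solution,
    euclidean_distance,
    focal_points,
    generate_evaluation_set,
    greedy_solution,
    legal_cells,
    random_board,
    score_game,
)
from bargaining_table.errors import (
    AssignmentShapeError,
    ConstraintInfeasibleError,
    FocalTieError,
)
from bargaining_table.game import (
    board_from_dict,
    board_to_dict,
    evaluation_set_totals,
    mirror_board,
    strategic_position_of,
)

# ---------------------------------------------------------------------------
# strategies
# ---------------------------------------------------------------------------

DEFAULT = BoardConfig()
NON_TIE_CELLS = [
    c for c in legal_cells(DEFAULT) if c.x != 5  # x=5 is the equidistant column
]


@st.composite
def boards(draw, max_discs=8):
    n = draw(st.integers(1, max_discs))
    idx = draw(
        st.lists(st.integers(0, len(NON_TIE_CELLS) - 1), min_size=n, max_size=n, unique=True)
    )
    values = draw(st.lists(st.integers(1, 5), min_size=n, max_size=n))
    return GameBoard(
        config=DEFAULT,
        discs=tuple(Disc(NON_TIE_CELLS[i], v) for i, v in zip(idx, values)),
    )


@st.composite
def board_with_assignments(draw, max_discs=8):
    board = draw(boards(max_discs))
    labels = st.lists(
        st.sampled_from([Player.P1, Player.P2]),
        min_size=board.n_discs,
        max_size=board.n_discs,
    )
    return board, AssignmentVector(tuple(draw(labels))), AssignmentVector(tuple(draw(labels)))


# ---------------------------------------------------------------------------
# distances and scoring
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "a, b, expected",
    [((1, 5), (2, 5), 1.0), ((1, 1), (4, 5), 5.0), ((3, 3), (3, 3), 0.0)],
)
def test_euclidean_distance_known_values(a, b, expected):
    assert euclidean_distance(GridPosition(*a), GridPosition(*b)) == expected


@pytest.mark.parametrize(
    "discs, c1, c2, expected",
    [
        # both agree: the agreed player collects the full disc value
        ([(3, 5, 5)], "11", "11", (5.0, 0.0)),
        # disagreement fines both players 20% of the value
        ([(3, 5, 5)], "1", "2", (-1.0, -1.0)),
        # mixed: agree on first disc to P2, disagree on the second
        ([(3, 5, 3), (4, 4, 4)], "21", "22", (-0.8, 2.2)),
    ],
)
def test_score_game_worked_examples(make_board, discs, c1, c2, expected):
    board = make_board(*discs)
    to_vec = lambda s: AssignmentVector(
        tuple(Player.P1 if ch == "1" else Player.P2 for ch in s[: board.n_discs])
    )
    out = score_game(board, to_vec(c1), to_vec(c2))
    assert (out.payoff_p1, out.payoff_p2) == pytest.approx(expected)


def test_score_game_rejects_shape_mismatch(make_board):
    board = make_board((3, 5, 2), (4, 4, 1))
    short = AssignmentVector((Player.P1,))
    with pytest.raises(AssignmentShapeError):
        score_game(board, short, greedy_solution(board, Player.P2))


@settings(max_examples=150, derandomize=True)
@given(board_with_assignments())
def test_payoff_identity_and_conservation(data):
    """payoff_p1 + payoff_p2 == agreed - 2*penalty*disagreed, and the
    agreed/disagreed values partition the board total."""
    board, a1, a2 = data
    out = score_game(board, a1, a2)
    pen = board.config.penalty_fraction
    assert out.payoff_p1 + out.payoff_p2 == pytest.approx(
        out.agreed_value - 2 * pen * out.disagreed_value
    )
    assert out.agreed_value + out.disagreed_value == board.total_points


@settings(max_examples=100, derandomize=True)
@given(board_with_assignments())
def test_relabeling_symmetry(data):
    """Swapping both players' labels and mirroring the board swaps payoffs."""
    board, a1, a2 = data
    out = score_game(board, a1, a2)
    swap = lambda a: AssignmentVector(tuple(c.other for c in a))
    out_swapped = score_game(board, swap(a2), swap(a1))
    assert out_swapped.payoff_p1 == pytest.approx(out.payoff_p2)
    assert out_swapped.payoff_p2 == pytest.approx(out.payoff_p1)


@settings(max_examples=100, derandomize=True)
@given(board_with_assignments(max_discs=3))
def test_score_matches_bruteforce_per_disc_oracle(data):
    """score_game agrees with an independent disc-by-disc evaluation."""
    board, a1, a2 = data
    pen = board.config.penalty_fraction
    p1 = p2 = 0.0
    for disc, c1, c2 in zip(board.discs, a1.choices, a2.choices):
        if c1 == c2:
            if c1 is Player.P1:
                p1 += disc.value
            else:
                p2 += disc.value
        else:
            p1 -= pen * disc.value
            p2 -= pen * disc.value
    out = score_game(board, a1, a2)
    assert (out.payoff_p1, out.payoff_p2) == pytest.approx((p1, p2))


# ---------------------------------------------------------------------------
# reference solutions
# ---------------------------------------------------------------------------


def test_closeness_assigns_to_strictly_nearer_square(make_board):
    board = make_board((3, 5, 1), (7, 2, 1))
    assert closeness_solution(board).choices == (Player.P1, Player.P2)


def test_closeness_raises_on_equidistant_disc(config):
    board = GameBoard(config=config, discs=(Disc(GridPosition(5, 1), 3),))
    with pytest.raises(FocalTieError):
        closeness_solution(board)


def test_greedy_takes_everything(make_board):
    board = make_board((3, 5, 1), (7, 2, 2), (1, 1, 3))
    assert greedy_solution(board, Player.P1).choices == (Player.P1,) * 3
    assert greedy_solution(board, Player.P2).choices == (Player.P2,) * 3


def test_greedy_vs_greedy_loses_fifth_of_total(make_board):
    board = make_board((3, 5, 4), (7, 2, 5))
    out = score_game(board, greedy_solution(board, Player.P1), greedy_solution(board, Player.P2))
    assert out.payoff_p1 == pytest.approx(-0.2 * board.total_points)
    assert out.payoff_p2 == pytest.approx(-0.2 * board.total_points)


@settings(max_examples=150, derandomize=True)
@given(board_with_assignments())
def test_greedy_dominance(data):
    """The greedy player's payoff is >= the opponent's for any opponent
    play, with equality iff the opponent concedes no disc."""
    board, opp, _ = data
    out = score_game(board, greedy_solution(board, Player.P1), opp)
    assert out.payoff_p1 >= out.payoff_p2 - 1e-12
    concedes = any(c is Player.P1 for c in opp)
    if not concedes:
        assert out.payoff_p1 == pytest.approx(out.payoff_p2)
    else:
        assert out.payoff_p1 > out.payoff_p2


@settings(max_examples=50, derandomize=True)
@given(boards())
def test_cooperative_conservation(board):
    """Mutual focal play splits the total with zero penalties."""
    focal = closeness_solution(board)
    out = score_game(board, focal, focal)
    assert out.disagreed_value == 0
    assert out.payoff_p1 + out.payoff_p2 == board.total_points


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def test_random_board_legality_and_determinism(config):
    b1 = random_board(7, config)
    b2 = random_board(7, config)
    assert b1 == b2
    for board in (b1, random_board(8, config), random_board(9, config)):
        positions = [d.position for d in board.discs]
        assert len(set(positions)) == len(positions)
        assert config.r1 not in positions and config.r2 not in positions
        assert all(p.x != 5 for p in positions)  # no equidistant discs


def test_random_board_disc_count_uniform():
    gen = np.random.default_rng(0)
    counts = np.bincount(
        [random_board(gen).n_discs for _ in range(10_000)], minlength=9
    )[1:]
    # each count ~ Binomial(10000, 1/8): 3 sigma around the mean
    sigma = math.sqrt(10_000 * (1 / 8) * (7 / 8))
    assert np.all(np.abs(counts - 1250) < 3 * sigma)


def test_evaluation_set_satisfies_all_constraints(eval_boards):
    assert len(eval_boards) == 10
    assert evaluation_set_totals(eval_boards) == (52, 52)
    for side in (Player.P1, Player.P2):
        positions = sorted(strategic_position_of(b, side) for b in eval_boards)
        assert positions == [-1] * 4 + [0] * 2 + [1] * 4


def test_evaluation_set_reproducible_and_seed_sensitive(eval_boards):
    assert generate_evaluation_set(0) == eval_boards
    assert generate_evaluation_set(1) != eval_boards


def test_evaluation_set_zero_budget_errors():
    with pytest.raises(ConstraintInfeasibleError):
        generate_evaluation_set(0, max_iter=0)


def test_mirror_board_swaps_roles(make_board):
    board = make_board((3, 5, 2), (4, 2, 5))
    mirrored = mirror_board(board)
    assert focal_points(board) == tuple(reversed(focal_points(mirrored)))
    assert strategic_position_of(board, Player.P1) == strategic_position_of(
        mirrored, Player.P2
    )


def test_board_json_roundtrip(make_board):
    board = make_board((3, 5, 2), (7, 2, 5))
    data = board_to_dict(board)
    assert data["r1"] == [2, 5] and data["penalty_fraction"] == 0.2
    assert board_from_dict(data) == board


@pytest.mark.parametrize(
    "discs",
    [
        [],  # empty board
        [(3, 5, 1)] * 2,  # duplicate position
        [(2, 5, 1)],  # on a square
        [(3, 5, 6)],  # value out of range
    ],
)
def test_board_validation_rejects_illegal_boards(config, discs):
    with pytest.raises((ValueError, TypeError)):
        GameBoard(
            config=config,
            discs=tuple(Disc(GridPosition(x, y), v) for x, y, v in discs),
        )
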