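import numpy as np
import pytest

from bargaining_table import (
    BoardConfig,
    Disc,
    GameBoard,
    GridPosition,
)


@pytest.fixture(scope="session")
def config() -> BoardConfig:
    return BoardConfig()


@pytest.fixture
def make_board(config):
    """Board factory from (x, y, value) triples on the default geometry."""

    def _make(*discs: tuple[int, int, int]) -> GameBoard:
        return GameBoard(
            config=config,
            discs=tuple(Disc(GridPosition(x, y), v) for x, y, v in discs),
        )

    return _make


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def eval_boards():
    from bargaining_table import generate_evaluation_set

    return generate_evaluation_set(0)
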