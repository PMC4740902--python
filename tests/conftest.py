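import numpy as np
import pytest

from rpslab.core import Item, Session, Trial

# Hand-worked single-block 9-trial session.  Player / computer items:
#   1 R/R draw   2 P/R win    3 P/S lose
#   4 R/P lose   5 S/P win    6 S/S draw
#   7 R/S win    8 R/R draw   9 R/S win
HAND_ITEMS = [
    ("R", "R"), ("P", "R"), ("P", "S"),
    ("R", "P"), ("S", "P"), ("S", "S"),
    ("R", "S"), ("R", "R"), ("R", "S"),
]


@pytest.fixture
def hand_session() -> Session:
    trials = [
        Trial.play(1, i + 1, Item.from_label(p), Item.from_label(c))
        for i, (p, c) in enumerate(HAND_ITEMS)
    ]
    return Session(participant_id="hand", trials=trials)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)


def random_session(rng: np.random.Generator, n_blocks: int, block_length: int,
                   participant_id: str = "rand") -> Session:
    """Uniformly random items on both sides; used to feed the table oracles."""
    trials = []
    for block in range(1, n_blocks + 1):
        for idx in range(1, block_length + 1):
            trials.append(
                Trial.play(block, idx, Item(rng.integers(3)), Item(rng.integers(3)))
            )
    return Session(participant_id=participant_id, trials=trials)
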