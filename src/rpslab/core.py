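"""Game core for iterated Rock-Paper-Scissors.

Encodes the non-transitive three-cycle: Rock beats Scissors, Paper beats
Rock, Scissors beats Paper.  Items carry the fixed indices Rock=0, Paper=1,
Scissors=2 so that +1 (mod 3) is the "upgrade" direction (the item that
beats you) and -1 (mod 3) is the "downgrade" direction (the item you beat).
With that encoding, outcome resolution and the stay/upgrade/downgrade
transition classification are the same modular difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum, IntEnum
from typing import Iterator


class Item(IntEnum):
    """One of the three cyclically ordered game symbols."""

    ROCK = 0
    PAPER = 1
    SCISSORS = 2

    @property
    def char(self) -> str:
        """Single-character serialization: R, P or S."""
        return "RPS"[int(self)]

    @classmethod
    def from_label(cls, label: str | int | "Item") -> "Item":
        """Parse an item from R/P/S or a full word, case-insensitively."""
        if isinstance(label, Item):
            return label
        if isinstance(label, int):
            return cls(label)
        key = str(label).strip().upper()
        mapping = {
            "R": cls.ROCK, "ROCK": cls.ROCK,
            "P": cls.PAPER, "PAPER": cls.PAPER,
            "S": cls.SCISSORS, "SCISSORS": cls.SCISSORS,
        }
        try:
            return mapping[key]
        except KeyError:
            raise ValueError(f"not a Rock-Paper-Scissors item: {label!r}") from None


class Outcome(str, Enum):
    """Trial outcome, always from the player's (participant's) perspective."""

    WIN = "win"
    LOSE = "lose"
    DRAW = "draw"

    @classmethod
    def from_label(cls, label: str | "Outcome") -> "Outcome":
        if isinstance(label, Outcome):
            return label
        try:
            return cls(str(label).strip().lower())
        except ValueError:
            raise ValueError(f"not an outcome: {label!r}") from None


class Strategy(str, Enum):
    """Inter-trial transition class of the player's own item choice.

    ``stay`` repeats the previous item; ``upgrade`` plays the item that
    would have beaten it; ``downgrade`` plays the item it would have beaten.
    """

    STAY = "stay"
    UPGRADE = "upgrade"
    DOWNGRADE = "downgrade"


#: Canonical orderings used by every table and ANOVA layout in the package.
ITEMS: tuple[Item, ...] = (Item.ROCK, Item.PAPER, Item.SCISSORS)
OUTCOMES: tuple[Outcome, ...] = (Outcome.WIN, Outcome.LOSE, Outcome.DRAW)
STRATEGIES: tuple[Strategy, ...] = (Strategy.STAY, Strategy.UPGRADE, Strategy.DOWNGRADE)


def resolve_outcome(player: Item, computer: Item) -> Outcome:
    """Resolve one round from the player's perspective.

    ``(player - computer) mod 3`` is 0 for a draw, 1 when the player's item
    beats the computer's (it sits one step up the cycle), 2 for a loss.
    """
    player = Item.from_label(player)
    computer = Item.from_label(computer)
    return (Outcome.DRAW, Outcome.WIN, Outcome.LOSE)[(player - computer) % 3]


def upgrade_of(item: Item) -> Item:
    """The item that beats ``item`` (Rock→Paper→Scissors→Rock)."""
    return Item((Item.from_label(item) + 1) % 3)


def downgrade_of(item: Item) -> Item:
    """The item that ``item`` beats; inverse of :func:`upgrade_of`."""
    return Item((Item.from_label(item) - 1) % 3)


def apply_strategy(item: Item, strategy: Strategy) -> Item:
    """Transform an item by a stay/upgrade/downgrade move."""
    if strategy is Strategy.STAY:
        return Item.from_label(item)
    if strategy is Strategy.UPGRADE:
        return upgrade_of(item)
    if strategy is Strategy.DOWNGRADE:
        return downgrade_of(item)
    raise ValueError(f"not a strategy: {strategy!r}")


def classify_transition(prev: Item, next_: Item) -> Strategy:
    """Classify the player's move from trial n to n+1.

    Same modular difference as :func:`resolve_outcome`: 0 → stay,
    +1 → upgrade, +2 (= −1) → downgrade.
    """
    prev = Item.from_label(prev)
    next_ = Item.from_label(next_)
    return STRATEGIES[(next_ - prev) % 3]


@dataclass(frozen=True)
class Trial:
    """One resolved round: block, 1-based index within block, both items."""

    block: int
    index_in_block: int
    player: Item
    computer: Item
    outcome: Outcome

    def __post_init__(self) -> None:
        if self.block < 1 or self.index_in_block < 1:
            raise ValueError("block and index_in_block are 1-based positive integers")
        expected = resolve_outcome(self.player, self.computer)
        if self.outcome is not expected:
            raise ValueError(
                f"inconsistent outcome for block {self.block} trial "
                f"{self.index_in_block}: {self.player.name} vs {self.computer.name} "
                f"resolves to {expected.value!r}, got {self.outcome.value!r}"
            )

    @classmethod
    def play(cls, block: int, index_in_block: int, player: Item, computer: Item) -> "Trial":
        """Build a trial with the outcome resolved from the two items."""
        player = Item.from_label(player)
        computer = Item.from_label(computer)
        return cls(block, index_in_block, player, computer, resolve_outcome(player, computer))


@dataclass
class Session:
    """All trials for one participant, grouped into consecutively indexed blocks."""

    participant_id: str
    trials: list[Trial] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: dict[int, int] = {}
        for t in self.trials:
            expected = seen.get(t.block, 0) + 1
            if t.index_in_block != expected:
                raise ValueError(
                    f"session {self.participant_id!r}: block {t.block} trial "
                    f"indices must be consecutive from 1; expected {expected}, "
                    f"got {t.index_in_block}"
                )
            seen[t.block] = t.index_in_block

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def block_ids(self) -> list[int]:
        out: list[int] = []
        for t in self.trials:
            if not out or out[-1] != t.block:
                out.append(t.block)
        return out

    def blocks(self) -> Iterator[list[Trial]]:
        """Yield trials one block at a time, in session order."""
        current: list[Trial] = []
        for t in self.trials:
            if current and current[-1].block != t.block:
                yield current
                current = []
            current.append(t)
        if current:
            yield current


@dataclass
class Cohort:
    """A set of sessions, one per participant."""

    sessions: list[Session] = field(default_factory=list)

    def __iter__(self) -> Iterator[Session]:
        return iter(self.sessions)

    def __len__(self) -> int:
        return len(self.sessions)

    @property
    def participant_ids(self) -> list[str]:
        return [s.participant_id for s in self.sessions]
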