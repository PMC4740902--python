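"""Playing agents: the equilibrium computer opponent, outcome-conditioned
switch agents, and an adaptive frequency-counting exploiter.

The computer opponent of the study design is a *balanced schedule*: each
block is a uniformly shuffled multiset containing each item an exact number
of times (25 per 75-trial block), i.e. a mixed-strategy equilibrium enforced
by exact counts rather than i.i.d. sampling.  An i.i.d. uniform agent is
provided for comparison.

The switch agent is the behavioural model: given the previous trial's
outcome it samples a stay/upgrade/downgrade move from a row-stochastic
policy table, with an optional "momentum" probability of simply repeating
the previous move when that move was a cyclic shift (upgrade or downgrade).
Momentum deliberately never applies after a stay, mirroring the asymmetry
that only the two cyclic-change strategies perpetuate themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    ITEMS,
    OUTCOMES,
    STRATEGIES,
    Item,
    Outcome,
    Session,
    Strategy,
    Trial,
    apply_strategy,
    resolve_outcome,
    upgrade_of,
)

_OUTCOME_ROW = {o: i for i, o in enumerate(OUTCOMES)}
_STRATEGY_COL = {s: i for i, s in enumerate(STRATEGIES)}


# ---------------------------------------------------------------------------
# Balanced (equilibrium) schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BalancedScheduleSpec:
    """Design of the computer's play: each block holds each item exactly
    ``count_per_item`` times, shuffled uniformly at random."""

    block_length: int = 75
    count_per_item: int = 25
    n_blocks: int = 3

    def __post_init__(self) -> None:
        if self.block_length <= 0 or self.count_per_item <= 0 or self.n_blocks <= 0:
            raise ValueError("schedule dimensions must be positive")
        if 3 * self.count_per_item != self.block_length:
            raise ValueError(
                f"block_length must equal 3 x count_per_item "
                f"(got {self.block_length} != 3 x {self.count_per_item})"
            )


def make_balanced_schedule(
    spec: BalancedScheduleSpec, rng: np.random.Generator
) -> list[list[Item]]:
    """Independent uniformly shuffled balanced blocks, one list per block."""
    base = [item for item in ITEMS for _ in range(spec.count_per_item)]
    blocks: list[list[Item]] = []
    for _ in range(spec.n_blocks):
        order = rng.permutation(len(base))
        blocks.append([base[i] for i in order])
    return blocks


# ---------------------------------------------------------------------------
# Outcome-conditioned switch policy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SwitchPolicy:
    """P(strategy at n+1 | outcome at n) with momentum.

    Parameters
    ----------
    theta
        3x3 row-stochastic table; rows ordered (win, lose, draw), columns
        ordered (stay, upgrade, downgrade).
    kappa
        Probability of repeating the previous transition's strategy instead
        of sampling from ``theta``; applies only when the previous strategy
        was upgrade or downgrade.
    pi0
        Item distribution for history-free trials (the first trial of each
        block); defaults to uniform.
    """

    theta: tuple[tuple[float, float, float], ...]
    kappa: float = 0.0
    pi0: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)

    def __post_init__(self) -> None:
        th = np.asarray(self.theta, dtype=float)
        if th.shape != (3, 3):
            raise ValueError("theta must be a 3x3 table (win/lose/draw x stay/upgrade/downgrade)")
        if (th < 0).any():
            raise ValueError("theta entries must be nonnegative")
        if not np.allclose(th.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"theta rows must sum to 1 within 1e-9, got {th.sum(axis=1)}")
        p0 = np.asarray(self.pi0, dtype=float)
        if p0.shape != (3,) or (p0 < 0).any() or not np.isclose(p0.sum(), 1.0, atol=1e-9):
            raise ValueError("pi0 must be a length-3 probability vector")
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError("kappa must lie in [0, 1]")
        object.__setattr__(self, "theta", tuple(tuple(map(float, row)) for row in th))
        object.__setattr__(self, "pi0", tuple(map(float, p0)))

    @property
    def theta_array(self) -> np.ndarray:
        return np.asarray(self.theta, dtype=float)

    def theta_row(self, outcome: Outcome) -> np.ndarray:
        return self.theta_array[_OUTCOME_ROW[outcome]]

    def to_mapping(self) -> dict:
        """Plain config mapping (theta row-major win/lose/draw x stay/upgrade/downgrade)."""
        return {
            "theta": [x for row in self.theta for x in row],
            "kappa": self.kappa,
            "pi0": list(self.pi0),
        }

    @classmethod
    def from_mapping(cls, mapping: dict) -> "SwitchPolicy":
        flat = list(mapping["theta"])
        if len(flat) != 9:
            raise ValueError("theta must have 9 entries (row-major 3x3)")
        theta = tuple(tuple(flat[3 * i : 3 * i + 3]) for i in range(3))
        return cls(
            theta=theta,
            kappa=float(mapping.get("kappa", 0.0)),
            pi0=tuple(mapping.get("pi0", (1 / 3, 1 / 3, 1 / 3))),
        )


def switch_agent_choose(
    prev_item: Item | None,
    prev_outcome: Outcome | None,
    prev_strategy: Strategy | None,
    policy: SwitchPolicy,
    rng: np.random.Generator,
) -> Item:
    """One choice of the outcome-conditioned switch model.

    History-free trials sample from ``pi0``.  Otherwise, with probability
    ``kappa`` (only when the previous move was a cyclic shift) the previous
    strategy is reapplied; else a strategy is drawn from the theta row for
    the previous outcome.  The returned item is the previous item
    transformed by that strategy.
    """
    if prev_item is None:
        return ITEMS[rng.choice(3, p=np.asarray(policy.pi0))]
    if prev_outcome is None:
        raise ValueError("prev_outcome required when prev_item is given")
    if (
        prev_strategy is not None
        and prev_strategy is not Strategy.STAY
        and policy.kappa > 0
        and rng.random() < policy.kappa
    ):
        strategy = prev_strategy
    else:
        strategy = STRATEGIES[rng.choice(3, p=policy.theta_row(prev_outcome))]
    return apply_strategy(prev_item, strategy)


# ---------------------------------------------------------------------------
# Agent interface and implementations
# ---------------------------------------------------------------------------

class Agent:
    """Interface for :func:`play_match`: choose an item, observe the result.

    ``observe`` receives the agent's own item, the opponent's item, and the
    outcome from the agent's own perspective.  ``reset_block`` marks a block
    boundary; the inter-trial history of the study design does not cross
    blocks.
    """

    def reset_block(self) -> None:  # pragma: no cover - trivial default
        pass

    def choose(self, rng: np.random.Generator) -> Item:
        raise NotImplementedError

    def observe(self, own: Item, opponent: Item, outcome: Outcome) -> None:
        pass


class ScheduleAgent(Agent):
    """Plays a precomputed balanced schedule (the study's computer opponent)."""

    def __init__(self, spec: BalancedScheduleSpec, rng: np.random.Generator):
        self._blocks = make_balanced_schedule(spec, rng)
        self._block_idx = -1
        self._pos = 0

    def reset_block(self) -> None:
        self._block_idx += 1
        self._pos = 0
        if self._block_idx >= len(self._blocks):
            raise RuntimeError("schedule exhausted: more blocks requested than scheduled")

    def choose(self, rng: np.random.Generator) -> Item:
        if self._block_idx < 0:
            self.reset_block()
        item = self._blocks[self._block_idx][self._pos]
        self._pos += 1
        return item


class UniformRandomAgent(Agent):
    """I.i.d. uniform play; the unconstrained equilibrium variant."""

    def choose(self, rng: np.random.Generator) -> Item:
        return ITEMS[rng.integers(3)]


class SwitchAgent(Agent):
    """Stateful wrapper around :func:`switch_agent_choose`."""

    def __init__(self, policy: SwitchPolicy):
        self.policy = policy
        self._prev_item: Item | None = None
        self._prev_outcome: Outcome | None = None
        self._prev_strategy: Strategy | None = None

    def reset_block(self) -> None:
        self._prev_item = None
        self._prev_outcome = None
        self._prev_strategy = None

    def choose(self, rng: np.random.Generator) -> Item:
        item = switch_agent_choose(
            self._prev_item, self._prev_outcome, self._prev_strategy, self.policy, rng
        )
        if self._prev_item is not None:
            # Record the realised move class, whichever branch produced it.
            from .core import classify_transition

            self._prev_strategy = classify_transition(self._prev_item, item)
        self._prev_item = item
        return item

    def observe(self, own: Item, opponent: Item, outcome: Outcome) -> None:
        self._prev_outcome = outcome


@dataclass
class PredictorState:
    """Smoothed transition counts of an opponent, indexed by the opponent's
    previous (item, outcome-from-their-perspective) context."""

    smoothing: float = 1.0
    counts: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.counts is None:
            # axes: prev item (3) x prev outcome (3) x next item (3)
            self.counts = np.full((3, 3, 3), float(self.smoothing))

    def update(self, prev_item: Item, prev_outcome: Outcome, next_item: Item) -> None:
        self.counts[int(prev_item), _OUTCOME_ROW[prev_outcome], int(next_item)] += 1.0

    def predict(
        self, prev_item: Item, prev_outcome: Outcome, rng: np.random.Generator
    ) -> Item:
        """Modal next item for the context; ties broken uniformly at random."""
        row = self.counts[int(prev_item), _OUTCOME_ROW[prev_outcome]]
        best = np.flatnonzero(row == row.max())
        return ITEMS[int(rng.choice(best))]


def exploiter_choose(
    state: PredictorState,
    opp_prev_item: Item | None,
    opp_prev_outcome: Outcome | None,
    rng: np.random.Generator,
) -> Item:
    """Best-respond to the predicted opponent item (uniform when history-free)."""
    if opp_prev_item is None or opp_prev_outcome is None:
        return ITEMS[rng.integers(3)]
    return upgrade_of(state.predict(opp_prev_item, opp_prev_outcome, rng))


_INVERT = {Outcome.WIN: Outcome.LOSE, Outcome.LOSE: Outcome.WIN, Outcome.DRAW: Outcome.DRAW}


class ExploiterAgent(Agent):
    """Adaptive opponent: counts the other player's outcome-conditioned item
    transitions and plays the counter to the modal prediction.

    Learned counts persist across blocks; the conditioning context does not
    (block boundaries break the opponent's own inter-trial history).
    """

    def __init__(self, smoothing: float = 1.0):
        self.state = PredictorState(smoothing=smoothing)
        self._ctx: tuple[Item, Outcome] | None = None

    def reset_block(self) -> None:
        self._ctx = None

    def choose(self, rng: np.random.Generator) -> Item:
        if self._ctx is None:
            return exploiter_choose(self.state, None, None, rng)
        return exploiter_choose(self.state, self._ctx[0], self._ctx[1], rng)

    def observe(self, own: Item, opponent: Item, outcome: Outcome) -> None:
        opp_outcome = _INVERT[outcome]
        if self._ctx is not None:
            self.state.update(self._ctx[0], self._ctx[1], opponent)
        self._ctx = (opponent, opp_outcome)


def play_match(
    agent_a: Agent,
    agent_b: Agent,
    n_blocks: int,
    block_length: int,
    seed: int | np.random.Generator,
    participant_id: str = "a",
) -> Session:
    """Run a full match and return the Session from agent_a's perspective.

    Both agents draw from one seeded stream and observe every trial
    incrementally; outcomes are resolved by the game core.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    trials: list[Trial] = []
    for block in range(1, n_blocks + 1):
        agent_a.reset_block()
        agent_b.reset_block()
        for idx in range(1, block_length + 1):
            a = agent_a.choose(rng)
            b = agent_b.choose(rng)
            outcome = resolve_outcome(a, b)
            trials.append(Trial(block, idx, a, b, outcome))
            agent_a.observe(a, b, outcome)
            agent_b.observe(b, a, _INVERT[outcome])
    return Session(participant_id=participant_id, trials=trials)
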