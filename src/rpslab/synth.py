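"""Synthetic cohort generator emulating the study design.

The study deposited no trial-level human data, so analyses here run on
synthetic cohorts: 31 participants x 3 blocks x 75 trials against a
balanced-schedule computer opponent (each item exactly 25 times per block).
Participants are outcome-conditioned switch agents whose policy reproduces
the qualitative structure of the reported behaviour: after a win, staying
is the most likely move; after a loss, switching dominates with downgrading
the modal move and staying minimal; after a draw, upgrading is modal with
staying minimal; and cyclic moves carry momentum (a tendency to repeat an
upgrade or downgrade on the next transition).

The preset theta constants are synthetic: they satisfy the reported
argmax ordering but the magnitudes are package choices, since the source
figures are graphical only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .agents import (
    BalancedScheduleSpec,
    ScheduleAgent,
    SwitchAgent,
    SwitchPolicy,
    play_match,
)
from .core import Cohort, Session

#: Stochastic preset matching the reported argmax structure; constants are
#: synthetic (see module docstring).
PAPER_LIKE = SwitchPolicy(
    theta=(
        (0.40, 0.30, 0.30),  # win: stay maximal
        (0.24, 0.34, 0.42),  # lose: downgrade maximal, stay minimal
        (0.26, 0.44, 0.30),  # draw: upgrade maximal, stay minimal
    ),
    kappa=0.15,
)

#: Degenerate limit of the same structure: win->stay, lose->downgrade,
#: draw->upgrade with certainty.  This is the deterministic generalised
#: win-stay lose-shift rule; it implies the emergent "Rock after the
#: computer's Scissors" regularity on every within-block transition.
WSLS_DETERMINISTIC = SwitchPolicy(
    theta=(
        (1.0, 0.0, 0.0),
        (0.0, 0.0, 1.0),
        (0.0, 1.0, 0.0),
    ),
    kappa=0.0,
)

#: Memoryless equilibrium play expressed in the same parameterisation.
UNIFORM = SwitchPolicy(
    theta=(
        (1 / 3, 1 / 3, 1 / 3),
        (1 / 3, 1 / 3, 1 / 3),
        (1 / 3, 1 / 3, 1 / 3),
    ),
    kappa=0.0,
)

PRESETS: dict[str, SwitchPolicy] = {
    "paper-like": PAPER_LIKE,
    "uniform": UNIFORM,
    "wsls-deterministic": WSLS_DETERMINISTIC,
}


@dataclass(frozen=True)
class CohortConfig:
    """Cohort dimensions and behavioural model.

    Defaults reproduce the study design: 31 participants, 3 blocks of 75
    trials, computer playing each item exactly 25 times per block.
    ``concentration`` controls Dirichlet jitter of the policy's theta rows
    across participants (higher = less heterogeneity; ``None`` or ``inf``
    = all participants share theta exactly).
    """

    n_participants: int = 31
    n_blocks: int = 3
    block_length: int = 75
    policy: SwitchPolicy = PAPER_LIKE
    concentration: float | None = 200.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.block_length % 3 != 0:
            raise ValueError("block_length must be divisible by 3")
        if self.concentration is not None and self.concentration <= 0:
            raise ValueError("concentration must be positive (or None for no jitter)")

    @property
    def schedule_spec(self) -> BalancedScheduleSpec:
        return BalancedScheduleSpec(
            block_length=self.block_length,
            count_per_item=self.block_length // 3,
            n_blocks=self.n_blocks,
        )


def jitter_policy(
    policy: SwitchPolicy, concentration: float | None, rng: np.random.Generator
) -> SwitchPolicy:
    """Draw a participant-level policy around ``policy``.

    Each theta row r is replaced by a Dirichlet(concentration * r) draw,
    which keeps rows stochastic by construction.  Rows containing zeros
    (deterministic presets) pass through unchanged, as do all rows when
    concentration is None/inf.
    """
    if concentration is None or math.isinf(concentration):
        return policy
    rows = []
    for row in policy.theta_array:
        if (row <= 0).any():
            rows.append(tuple(row))
        else:
            rows.append(tuple(rng.dirichlet(concentration * row)))
    return replace(policy, theta=tuple(rows))


def generate_session(
    participant_id: str,
    config: CohortConfig,
    rng: np.random.Generator,
    policy: SwitchPolicy | None = None,
) -> Session:
    """Simulate one participant-vs-computer session under the study design."""
    policy = policy if policy is not None else config.policy
    computer = ScheduleAgent(config.schedule_spec, rng)
    participant = SwitchAgent(policy)
    return play_match(
        participant,
        computer,
        n_blocks=config.n_blocks,
        block_length=config.block_length,
        seed=rng,
        participant_id=participant_id,
    )


def generate_cohort(config: CohortConfig, seed: int | None = None) -> Cohort:
    """Simulate the full cohort; per-participant policies are jittered draws
    around the configured policy."""
    seed = seed if seed is not None else config.seed
    if seed is None:
        raise ValueError("a seed is required to generate a cohort")
    rng = np.random.default_rng(seed)
    sessions = []
    for i in range(1, config.n_participants + 1):
        pid = f"p{i:02d}"
        policy = jitter_policy(config.policy, config.concentration, rng)
        sessions.append(generate_session(pid, config, rng, policy=policy))
    return Cohort(sessions=sessions)
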