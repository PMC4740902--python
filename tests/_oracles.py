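"""Independent brute-force oracles used by the test suite.

Everything here is written from the game's verbal rules and the
definitional statistics formulas, deliberately avoiding the package's own
modular-arithmetic and inclusion-exclusion implementations, so the two
routes can disagree.
"""

from __future__ import annotations

import numpy as np

from rpslab.core import Item, Outcome, Session, Strategy

# The beats-relation written literally from the three verbal rules:
# Rock wins over Scissors, Paper wins over Rock, Scissors wins over Paper.
BEATS = {
    (Item.ROCK, Item.SCISSORS),
    (Item.PAPER, Item.ROCK),
    (Item.SCISSORS, Item.PAPER),
}


def rule_table_outcome(player: Item, computer: Item) -> Outcome:
    if player == computer:
        return Outcome.DRAW
    if (player, computer) in BEATS:
        return Outcome.WIN
    return Outcome.LOSE


def rule_table_transition(prev: Item, nxt: Item) -> Strategy:
    """Stay if same; upgrade if the new item beats the old; else downgrade."""
    if prev == nxt:
        return Strategy.STAY
    if (nxt, prev) in BEATS:
        return Strategy.UPGRADE
    return Strategy.DOWNGRADE


# ---------------------------------------------------------------------------
# Table recomputation by literal looping
# ---------------------------------------------------------------------------


def _blocks(session: Session) -> list[list]:
    out: dict[int, list] = {}
    for t in session.trials:
        out.setdefault(t.block, []).append(t)
    return [out[b] for b in sorted(out)]


def brute_marginals(session: Session) -> tuple[dict, dict]:
    items: dict[str, int] = {}
    outcomes: dict[str, int] = {}
    for t in session.trials:
        items[t.player.char] = items.get(t.player.char, 0) + 1
        outcomes[t.outcome.value] = outcomes.get(t.outcome.value, 0) + 1
    return items, outcomes


def brute_first_order(session: Session) -> dict[tuple[str, str, str], int]:
    """(item, outcome, strategy) -> count over within-block transitions."""
    counts: dict[tuple[str, str, str], int] = {}
    for block in _blocks(session):
        for a, b in zip(block, block[1:]):
            key = (
                a.player.char,
                rule_table_outcome(a.player, a.computer).value,
                rule_table_transition(a.player, b.player).value,
            )
            counts[key] = counts.get(key, 0) + 1
    return counts


def brute_second_order(session: Session) -> dict[tuple[str, str], int]:
    counts: dict[tuple[str, str], int] = {}
    for block in _blocks(session):
        for a, b, c in zip(block, block[1:], block[2:]):
            key = (
                rule_table_transition(a.player, b.player).value,
                rule_table_transition(b.player, c.player).value,
            )
            counts[key] = counts.get(key, 0) + 1
    return counts


def brute_computer_response(session: Session) -> dict[tuple[str, str], int]:
    counts: dict[tuple[str, str], int] = {}
    for block in _blocks(session):
        for a, b in zip(block, block[1:]):
            key = (a.computer.char, b.player.char)
            counts[key] = counts.get(key, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# Definitional sums of squares
# ---------------------------------------------------------------------------


def ss_oneway(y: np.ndarray) -> dict[str, float]:
    """Subjects-by-treatment decomposition from the textbook definitions."""
    n, k = y.shape
    grand = y.mean()
    ss_total = ((y - grand) ** 2).sum()
    ss_subj = sum(k * (y[s].mean() - grand) ** 2 for s in range(n))
    ss_treat = sum(n * (y[:, j].mean() - grand) ** 2 for j in range(k))
    ss_err = 0.0
    for s in range(n):
        for j in range(k):
            ss_err += (y[s, j] - y[s].mean() - y[:, j].mean() + grand) ** 2
    return {
        "total": ss_total,
        "subjects": ss_subj,
        "treatment": ss_treat,
        "error": ss_err,
    }


def ss_twoway_within(y: np.ndarray) -> dict[str, float]:
    """All SS terms of a subjects x A x B fully-within design, via explicit
    marginal-mean loops."""
    n, a, b = y.shape
    grand = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)
    m_ab = y.mean(axis=0)
    out = {
        "A": sum(n * b * (m_a[i] - grand) ** 2 for i in range(a)),
        "B": sum(n * a * (m_b[j] - grand) ** 2 for j in range(b)),
        "S": sum(a * b * (m_s[s] - grand) ** 2 for s in range(n)),
    }
    out["AS"] = sum(
        b * (m_sa[s, i] - m_s[s] - m_a[i] + grand) ** 2
        for s in range(n) for i in range(a)
    )
    out["BS"] = sum(
        a * (m_sb[s, j] - m_s[s] - m_b[j] + grand) ** 2
        for s in range(n) for j in range(b)
    )
    out["AB"] = sum(
        n * (m_ab[i, j] - m_a[i] - m_b[j] + grand) ** 2
        for i in range(a) for j in range(b)
    )
    out["ABS"] = sum(
        (
            y[s, i, j]
            - m_sa[s, i] - m_sb[s, j] - m_ab[i, j]
            + m_s[s] + m_a[i] + m_b[j] - grand
        ) ** 2
        for s in range(n) for i in range(a) for j in range(b)
    )
    out["total"] = ((y - grand) ** 2).sum()
    return out


def gg_epsilon_box(y: np.ndarray) -> float:
    """Box's epsilon for a one-way layout from the double-centered covariance."""
    n, k = y.shape
    s = np.cov(y, rowvar=False)
    centered = s - s.mean(axis=0) - s.mean(axis=1)[:, None] + s.mean()
    return float(np.trace(centered) ** 2 / ((k - 1) * (centered**2).sum()))
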