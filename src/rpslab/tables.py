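"""Descriptive inter-trial analysis: marginal frequencies, first- and
second-order conditional strategy tables, the computer-item-conditioned
response table, and the arc-sine variance-stabilising transform.

Trial accounting follows the study exactly: transitions are formed only
between consecutive trials *within* a block, so a 3x75 session contributes
225 - 3 = 222 first-order transitions and 225 - 6 = 219 second-order
transition pairs.  All conditional tables are cell-normalised (proportions
within a conditioning cell sum to 1), which is what renders the
conditioning factors' main effects vacuous in the downstream ANOVAs.

Empty conditioning cells are reported as missing (NaN proportion with a
zero denominator), never as zero; cohort aggregation averages each cell
over the participants that possess it and reports how many do.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import (
    ITEMS,
    OUTCOMES,
    STRATEGIES,
    Cohort,
    Item,
    Outcome,
    Session,
    Strategy,
    classify_transition,
)

_ITEM_LABELS = [i.char for i in ITEMS]
_OUTCOME_LABELS = [o.value for o in OUTCOMES]
_STRATEGY_LABELS = [s.value for s in STRATEGIES]


def _within_block_pairs(session: Session) -> Iterable[tuple]:
    for block in session.blocks():
        for prev, nxt in zip(block, block[1:]):
            yield prev, nxt


def _within_block_triples(session: Session) -> Iterable[tuple]:
    for block in session.blocks():
        for a, b, c in zip(block, block[1:], block[2:]):
            yield a, b, c


def n_first_order_transitions(session: Session) -> int:
    """Number of within-block consecutive trial pairs (225-trial design: 222)."""
    return sum(1 for _ in _within_block_pairs(session))


def n_second_order_pairs(session: Session) -> int:
    """Number of within-block consecutive transition pairs (design: 219)."""
    return sum(1 for _ in _within_block_triples(session))


# ---------------------------------------------------------------------------
# Marginal item / outcome frequencies
# ---------------------------------------------------------------------------

def marginal_counts(session: Session) -> pd.DataFrame:
    """Counts and proportions of each item and each outcome over all trials.

    Returns a tidy frame with columns
    ``participant, kind, level, count, proportion`` (kind is "item" or
    "outcome"; item levels are R/P/S characters).
    """
    if session.n_trials == 0:
        raise ValueError("marginal_counts requires a nonempty session")
    item_counts = {lab: 0 for lab in _ITEM_LABELS}
    outcome_counts = {lab: 0 for lab in _OUTCOME_LABELS}
    for t in session.trials:
        item_counts[t.player.char] += 1
        outcome_counts[t.outcome.value] += 1
    n = session.n_trials
    rows = [
        {"participant": session.participant_id, "kind": "item", "level": lab,
         "count": c, "proportion": c / n}
        for lab, c in item_counts.items()
    ] + [
        {"participant": session.participant_id, "kind": "outcome", "level": lab,
         "count": c, "proportion": c / n}
        for lab, c in outcome_counts.items()
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# First-order: strategy at n+1 conditioned on (item, outcome) at n
# ---------------------------------------------------------------------------

def first_order_table(session: Session) -> pd.DataFrame:
    """Per-cell strategy proportions: P(strategy at n+1 | item, outcome at n).

    One row per (item, outcome, strategy) combination (27 rows).  ``n_cell``
    is the number of within-block transitions whose trial-n context falls in
    the cell; proportion is NaN when the cell is empty.
    """
    counts = np.zeros((3, 3, 3), dtype=int)  # item x outcome x strategy
    for prev, nxt in _within_block_pairs(session):
        s = classify_transition(prev.player, nxt.player)
        counts[int(prev.player), list(OUTCOMES).index(prev.outcome),
               list(STRATEGIES).index(s)] += 1
    cell_n = counts.sum(axis=2)
    rows = []
    for i, item in enumerate(ITEMS):
        for j, outcome in enumerate(OUTCOMES):
            for k, strat in enumerate(STRATEGIES):
                n = int(cell_n[i, j])
                rows.append({
                    "participant": session.participant_id,
                    "item": item.char,
                    "outcome": outcome.value,
                    "strategy": strat.value,
                    "count": int(counts[i, j, k]),
                    "n_cell": n,
                    "proportion": counts[i, j, k] / n if n else np.nan,
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Second-order: strategy at n+1 -> n+2 conditioned on strategy at n -> n+1
# ---------------------------------------------------------------------------

def second_order_table(session: Session) -> pd.DataFrame:
    """P(strategy n+1→n+2 | strategy n→n+1) over within-block triple runs."""
    counts = np.zeros((3, 3), dtype=int)
    strat_idx = {s: i for i, s in enumerate(STRATEGIES)}
    for a, b, c in _within_block_triples(session):
        s1 = classify_transition(a.player, b.player)
        s2 = classify_transition(b.player, c.player)
        counts[strat_idx[s1], strat_idx[s2]] += 1
    row_n = counts.sum(axis=1)
    rows = []
    for i, s1 in enumerate(STRATEGIES):
        for j, s2 in enumerate(STRATEGIES):
            n = int(row_n[i])
            rows.append({
                "participant": session.participant_id,
                "strategy_n1": s1.value,
                "strategy_n2": s2.value,
                "count": int(counts[i, j]),
                "n_row": n,
                "proportion": counts[i, j] / n if n else np.nan,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Computer-item-conditioned response table
# ---------------------------------------------------------------------------

def computer_response_table(session: Session) -> pd.DataFrame:
    """P(player item at n+1 | computer item at n), within block."""
    counts = np.zeros((3, 3), dtype=int)
    for prev, nxt in _within_block_pairs(session):
        counts[int(prev.computer), int(nxt.player)] += 1
    row_n = counts.sum(axis=1)
    rows = []
    for i, comp in enumerate(ITEMS):
        for j, player in enumerate(ITEMS):
            n = int(row_n[i])
            rows.append({
                "participant": session.participant_id,
                "computer_item": comp.char,
                "player_next": player.char,
                "count": int(counts[i, j]),
                "n_row": n,
                "proportion": counts[i, j] / n if n else np.nan,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Arc-sine transform
# ---------------------------------------------------------------------------

#: How the zero-proportion branch's printed formula is read: 1/(2y), the
#: standard small-sample correction.  Recorded in every run manifest.
ZERO_PROPORTION_READING = "1/(2*y)"


@dataclass(frozen=True)
class TransformedProportion:
    """Arc-sine transformed proportion with the branch that produced it."""

    x: float
    y: int
    value: float
    branch: str  # "positive" or "zero"


def arcsine_transform(x: float, y: int) -> TransformedProportion:
    """Variance-stabilising transform 2*asin(sqrt(x)) for a proportion.

    For x = 0 the zero branch substitutes the small-sample correction
    1/(2y), where y is the number of possible observations in the cell, so
    empty-but-possible cells map to a small positive angle instead of 0.
    Values lie in [0, pi] (radians).
    """
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"proportion must lie in [0, 1], got {x}")
    if y < 1:
        raise ValueError(f"cell size must be >= 1, got {y}")
    if x > 0:
        return TransformedProportion(x, int(y), 2.0 * math.asin(math.sqrt(x)), "positive")
    return TransformedProportion(
        x, int(y), 2.0 * math.asin(math.sqrt(1.0 / (2.0 * y))), "zero"
    )


def arcsine_values(proportions: np.ndarray, cell_sizes: np.ndarray) -> np.ndarray:
    """Vectorised arc-sine transform over a proportion array (NaN passes through)."""
    p = np.asarray(proportions, dtype=float)
    y = np.broadcast_to(np.asarray(cell_sizes, dtype=float), p.shape)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pos = ok & (p > 0)
    zero = ok & (p == 0)
    out[pos] = 2.0 * np.arcsin(np.sqrt(p[pos]))
    out[zero] = 2.0 * np.arcsin(np.sqrt(1.0 / (2.0 * y[zero])))
    return out


# ---------------------------------------------------------------------------
# Cohort aggregation and ANOVA-ready arrays
# ---------------------------------------------------------------------------

def aggregate_cohort(frames: Sequence[pd.DataFrame], keys: Sequence[str]) -> pd.DataFrame:
    """Unweighted per-cell mean of ``proportion`` across participants.

    Missing (empty) cells are excluded from their cell's mean;
    ``n_participants`` reports how many participants contribute to each
    cell, so the handling of empty cells is auditable.
    """
    if not frames:
        raise ValueError("aggregate_cohort requires at least one participant table")
    combined = pd.concat(frames, ignore_index=True)
    grouped = combined.groupby(list(keys), sort=False)["proportion"]
    out = grouped.agg(mean_proportion="mean", n_participants="count").reset_index()
    return out


def _pivot_array(
    frames: Sequence[pd.DataFrame],
    keys: Sequence[str],
    level_orders: Sequence[Sequence[str]],
    value: str = "proportion",
) -> np.ndarray:
    """Stack per-participant tidy tables into a (n_subjects, *shape) array."""
    shape = tuple(len(levels) for levels in level_orders)
    indexers = [{lab: i for i, lab in enumerate(levels)} for levels in level_orders]
    arrays = []
    for frame in frames:
        arr = np.full(shape, np.nan)
        for _, row in frame.iterrows():
            idx = tuple(ix[row[k]] for k, ix in zip(keys, indexers))
            arr[idx] = row[value]
        arrays.append(arr)
    return np.stack(arrays)


def cohort_first_order_array(
    cohort: Cohort, transform: bool = False
) -> tuple[np.ndarray, list[str]]:
    """Subjects x item x outcome x strategy proportion array for the
    three-way ANOVA; raises naming the missing cells if any participant has
    an empty conditioning cell."""
    frames = [first_order_table(s) for s in cohort]
    arr = _pivot_array(
        frames,
        ["item", "outcome", "strategy"],
        [_ITEM_LABELS, _OUTCOME_LABELS, _STRATEGY_LABELS],
    )
    if transform:
        # cell size = number of transitions in the conditioning cell
        sizes = _pivot_array(
            frames, ["item", "outcome", "strategy"],
            [_ITEM_LABELS, _OUTCOME_LABELS, _STRATEGY_LABELS], value="n_cell",
        ).clip(min=1)
        arr = arcsine_values(arr, sizes)
    _check_complete(arr, cohort.participant_ids,
                    [_ITEM_LABELS, _OUTCOME_LABELS, _STRATEGY_LABELS])
    return arr, cohort.participant_ids


def cohort_second_order_array(
    cohort: Cohort, transform: bool = False
) -> tuple[np.ndarray, list[str]]:
    """Subjects x strategy(n+1) x strategy(n+2) proportion array."""
    frames = [second_order_table(s) for s in cohort]
    arr = _pivot_array(
        frames, ["strategy_n1", "strategy_n2"], [_STRATEGY_LABELS, _STRATEGY_LABELS]
    )
    if transform:
        sizes = _pivot_array(
            frames, ["strategy_n1", "strategy_n2"],
            [_STRATEGY_LABELS, _STRATEGY_LABELS], value="n_row",
        ).clip(min=1)
        arr = arcsine_values(arr, sizes)
    _check_complete(arr, cohort.participant_ids, [_STRATEGY_LABELS, _STRATEGY_LABELS])
    return arr, cohort.participant_ids


def cohort_marginal_array(cohort: Cohort, kind: str, percent: bool = True) -> np.ndarray:
    """Subjects x 3 marginal frequencies (kind "item" or "outcome"), as
    percentages by default."""
    if kind not in ("item", "outcome"):
        raise ValueError("kind must be 'item' or 'outcome'")
    levels = _ITEM_LABELS if kind == "item" else _OUTCOME_LABELS
    rows = []
    for session in cohort:
        frame = marginal_counts(session)
        sub = frame[frame["kind"] == kind].set_index("level")["proportion"]
        rows.append([sub[lab] for lab in levels])
    arr = np.asarray(rows, dtype=float)
    return arr * 100.0 if percent else arr


def _check_complete(arr, participant_ids, level_orders) -> None:
    if not np.isnan(arr).any():
        return
    missing = []
    for flat in np.argwhere(np.isnan(arr)):
        pid = participant_ids[flat[0]]
        labels = tuple(level_orders[d][flat[d + 1]] for d in range(len(level_orders)))
        missing.append(f"{pid}:{'/'.join(labels)}")
    raise ValueError(
        "incomplete within-subjects layout; empty conditioning cells: "
        + ", ".join(missing)
    )
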