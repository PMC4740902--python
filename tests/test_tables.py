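"""Descriptive tables: trial accounting, hand-worked and brute-force
oracle agreement, normalization, aggregation, and the arc-sine transform."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import (
    brute_computer_response,
    brute_first_order,
    brute_marginals,
    brute_second_order,
)
from conftest import random_session
from rpslab.core import Session
from rpslab.synth import CohortConfig, PAPER_LIKE, generate_cohort
from rpslab.tables import (
    aggregate_cohort,
    arcsine_transform,
    arcsine_values,
    cohort_first_order_array,
    cohort_marginal_array,
    cohort_second_order_array,
    computer_response_table,
    first_order_table,
    marginal_counts,
    n_first_order_transitions,
    n_second_order_pairs,
    second_order_table,
)


# ---------------------------------------------------------------------------
# Trial accounting
# ---------------------------------------------------------------------------

def test_design_trial_accounting():
    """3 blocks x 75 trials: 222 first-order transitions, 219 second-order
    pairs (the first one/two trials of each block carry no history)."""
    session = generate_cohort(CohortConfig(n_participants=1, seed=1)).sessions[0]
    assert session.n_trials == 225
    assert n_first_order_transitions(session) == 222
    assert n_second_order_pairs(session) == 219
    assert first_order_table(session)["count"].sum() == 222
    assert second_order_table(session)["count"].sum() == 219


@settings(derandomize=True, max_examples=20)
@given(n_blocks=st.integers(1, 4), block_length=st.integers(3, 12),
       seed=st.integers(0, 10_000))
def test_accounting_generalizes(n_blocks, block_length, seed):
    session = random_session(np.random.default_rng(seed), n_blocks, block_length)
    total = n_blocks * block_length
    assert n_first_order_transitions(session) == total - n_blocks
    assert n_second_order_pairs(session) == total - 2 * n_blocks


# ---------------------------------------------------------------------------
# Hand-worked 9-trial session
# ---------------------------------------------------------------------------

def _cell(frame: pd.DataFrame, **levels) -> pd.DataFrame:
    mask = np.ones(len(frame), dtype=bool)
    for col, val in levels.items():
        mask &= frame[col] == val
    return frame[mask]


def test_hand_session_marginals(hand_session):
    frame = marginal_counts(hand_session)
    items = frame[frame["kind"] == "item"].set_index("level")["count"]
    outcomes = frame[frame["kind"] == "outcome"].set_index("level")["count"]
    assert items.to_dict() == {"R": 5, "P": 2, "S": 2}
    assert outcomes.to_dict() == {"win": 4, "lose": 2, "draw": 3}
    assert outcomes.sum() == items.sum() == 9


def test_hand_session_first_order(hand_session):
    frame = first_order_table(hand_session)
    assert frame["count"].sum() == 8
    # (Rock, draw) occurs twice: once followed by upgrade, once by stay
    cell = _cell(frame, item="R", outcome="draw").set_index("strategy")
    assert cell.loc["stay", "proportion"] == pytest.approx(0.5)
    assert cell.loc["upgrade", "proportion"] == pytest.approx(0.5)
    assert cell["n_cell"].eq(2).all()
    # single-transition cells
    assert _cell(frame, item="P", outcome="lose", strategy="downgrade")[
        "proportion"].item() == 1.0
    assert _cell(frame, item="S", outcome="draw", strategy="upgrade")[
        "proportion"].item() == 1.0
    # empty cell reported missing, not zero
    empty = _cell(frame, item="P", outcome="draw")
    assert empty["n_cell"].eq(0).all()
    assert empty["proportion"].isna().all()


def test_hand_session_second_order(hand_session):
    frame = second_order_table(hand_session).set_index(["strategy_n1", "strategy_n2"])
    assert frame["count"].sum() == 7
    assert frame.loc[("upgrade", "stay"), "proportion"] == 1.0
    for s2 in ("stay", "upgrade", "downgrade"):
        assert frame.loc[("stay", s2), "proportion"] == pytest.approx(1 / 3)
    assert frame.loc[("downgrade", "downgrade"), "proportion"] == pytest.approx(0.5)
    assert frame.loc[("downgrade", "stay"), "proportion"] == pytest.approx(0.5)


def test_hand_session_computer_response(hand_session):
    frame = computer_response_table(hand_session).set_index(
        ["computer_item", "player_next"])
    assert frame.loc[("R", "P"), "proportion"] == pytest.approx(2 / 3)
    assert frame.loc[("R", "R"), "proportion"] == pytest.approx(1 / 3)
    assert frame.loc[("P", "S"), "proportion"] == 1.0
    assert frame.loc[("S", "R"), "proportion"] == 1.0


# ---------------------------------------------------------------------------
# Brute-force oracle equivalence on small random sessions
# ---------------------------------------------------------------------------

@settings(derandomize=True, max_examples=30)
@given(seed=st.integers(0, 10_000), n_blocks=st.integers(1, 3),
       block_length=st.integers(3, 10))
def test_tables_match_brute_force(seed, n_blocks, block_length):
    """On sessions of <=10 trials per block every table equals a literal
    loop over trials applying the verbal definitions."""
    session = random_session(np.random.default_rng(seed), n_blocks, block_length)

    items, outcomes = brute_marginals(session)
    marg = marginal_counts(session)
    for kind, expected in (("item", items), ("outcome", outcomes)):
        got = marg[marg["kind"] == kind].set_index("level")["count"].to_dict()
        assert {k: v for k, v in got.items() if v} == expected

    fo = first_order_table(session)
    got_fo = {
        (r.item, r.outcome, r.strategy): r.count
        for r in fo.itertuples() if r.count
    }
    assert got_fo == brute_first_order(session)

    so = second_order_table(session)
    got_so = {
        (r.strategy_n1, r.strategy_n2): r.count for r in so.itertuples() if r.count
    }
    assert got_so == brute_second_order(session)

    cr = computer_response_table(session)
    got_cr = {
        (r.computer_item, r.player_next): r.count for r in cr.itertuples() if r.count
    }
    assert got_cr == brute_computer_response(session)


@settings(derandomize=True, max_examples=15)
@given(seed=st.integers(0, 10_000))
def test_nonempty_rows_normalized(seed):
    session = random_session(np.random.default_rng(seed), 3, 20)
    fo = first_order_table(session)
    sums = fo.groupby(["item", "outcome"])["proportion"].sum(min_count=1).dropna()
    assert np.allclose(sums, 1.0, atol=1e-9)
    so = second_order_table(session)
    sums = so.groupby("strategy_n1")["proportion"].sum(min_count=1).dropna()
    assert np.allclose(sums, 1.0, atol=1e-9)


def test_empty_session_rejected():
    with pytest.raises(ValueError, match="nonempty"):
        marginal_counts(Session(participant_id="x", trials=[]))


# ---------------------------------------------------------------------------
# Arc-sine transform
# ---------------------------------------------------------------------------

def test_arcsine_closed_forms():
    assert arcsine_transform(0.25, 10).value == pytest.approx(math.pi / 3)
    assert arcsine_transform(0.5, 10).value == pytest.approx(math.pi / 2)
    assert arcsine_transform(1.0, 10).value == pytest.approx(math.pi)
    zero = arcsine_transform(0.0, 50)
    assert zero.branch == "zero"
    assert zero.value == pytest.approx(2 * math.asin(math.sqrt(1 / 100)), abs=1e-12)
    assert zero.value == pytest.approx(0.2003, abs=5e-4)


@settings(derandomize=True, max_examples=50)
@given(st.tuples(st.floats(0.001, 0.999), st.floats(0.001, 0.999)))
def test_arcsine_strictly_increasing(pair):
    lo, hi = sorted(pair)
    if lo == hi:
        hi = min(1.0, hi + 1e-6)
    assert arcsine_transform(lo, 5).value < arcsine_transform(hi, 5).value


def test_arcsine_rejects_bad_inputs():
    with pytest.raises(ValueError):
        arcsine_transform(-0.1, 10)
    with pytest.raises(ValueError):
        arcsine_transform(1.1, 10)
    with pytest.raises(ValueError):
        arcsine_transform(0.5, 0)


def test_arcsine_values_vectorized_matches_scalar():
    p = np.array([0.0, 0.25, np.nan, 1.0])
    out = arcsine_values(p, np.array([50.0, 50.0, 50.0, 50.0]))
    assert out[0] == pytest.approx(arcsine_transform(0.0, 50).value)
    assert out[1] == pytest.approx(math.pi / 3)
    assert np.isnan(out[2])
    assert out[3] == pytest.approx(math.pi)


# ---------------------------------------------------------------------------
# Aggregation and ANOVA-ready arrays
# ---------------------------------------------------------------------------

def test_aggregate_single_participant_is_identity(hand_session):
    frame = second_order_table(hand_session)
    agg = aggregate_cohort([frame], ["strategy_n1", "strategy_n2"])
    merged = frame.merge(agg, on=["strategy_n1", "strategy_n2"])
    assert np.allclose(merged["proportion"], merged["mean_proportion"], equal_nan=True)
    assert (agg["n_participants"] == 1).all()


def test_aggregate_two_participants_means_and_missing():
    keys = ["k"]
    a = pd.DataFrame({"k": ["x", "y"], "proportion": [0.2, np.nan]})
    b = pd.DataFrame({"k": ["x", "y"], "proportion": [0.6, 0.4]})
    agg = aggregate_cohort([a, b], keys).set_index("k")
    assert agg.loc["x", "mean_proportion"] == pytest.approx(0.4)
    assert agg.loc["x", "n_participants"] == 2
    # missing cell excluded from the mean, participation count reported
    assert agg.loc["y", "mean_proportion"] == pytest.approx(0.4)
    assert agg.loc["y", "n_participants"] == 1


def test_cohort_arrays_shapes_and_recovery():
    cohort = generate_cohort(CohortConfig(seed=3))
    fo, pids = cohort_first_order_array(cohort)
    assert fo.shape == (31, 3, 3, 3) and len(pids) == 31
    assert np.allclose(fo.sum(axis=3), 1.0, atol=1e-9)
    so, _ = cohort_second_order_array(cohort)
    assert so.shape == (31, 3, 3)
    marg = cohort_marginal_array(cohort, "item")
    assert marg.shape == (31, 3)
    assert np.allclose(marg.sum(axis=1), 100.0)


def test_incomplete_layout_names_missing_cells():
    # 6-trial sessions leave most (item, outcome) cells empty
    cohort = generate_cohort(
        CohortConfig(n_participants=2, n_blocks=1, block_length=6, seed=4)
    )
    with pytest.raises(ValueError, match="empty conditioning cells"):
        cohort_first_order_array(cohort)


def test_cohort_mean_recovers_theta():
    """Unweighted per-cell cohort means of the strategy-by-outcome table
    stay within ±0.03 of the generating theta for a 31-participant cohort."""
    from rpslab.agents import SwitchPolicy

    config = CohortConfig(
        policy=SwitchPolicy(theta=PAPER_LIKE.theta, kappa=0.0),
        concentration=None, seed=11,
    )
    cohort = generate_cohort(config)
    fo, _ = cohort_first_order_array(cohort)
    by_outcome = fo.mean(axis=(0, 1))  # outcome x strategy
    assert np.abs(by_outcome - np.asarray(PAPER_LIKE.theta)).max() < 0.03
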