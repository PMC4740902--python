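"""Trial-log serialization and the simulate-and-analyse pipeline.

Trial logs are long-format UTF-8 CSV, one row per trial, with the header

    participant_id,block,trial,player_item,computer_item,outcome

Items are written as single characters R/P/S (full words accepted
case-insensitively on read); the outcome column is always written and is
validated on read against the game rule, so a corrupted or hand-edited log
fails loudly with the offending row named.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .anova import anova_table, rm_anova, rm_anova_oneway, tukey_hsd
from .core import (
    ITEMS,
    OUTCOMES,
    STRATEGIES,
    Cohort,
    Item,
    Outcome,
    Session,
    Trial,
    resolve_outcome,
)
from .synth import PRESETS, CohortConfig, SwitchPolicy, generate_cohort
from .tables import (
    ZERO_PROPORTION_READING,
    aggregate_cohort,
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

logger = logging.getLogger("rpslab")

TRIAL_LOG_COLUMNS = [
    "participant_id",
    "block",
    "trial",
    "player_item",
    "computer_item",
    "outcome",
]


# ---------------------------------------------------------------------------
# Trial-log CSV
# ---------------------------------------------------------------------------


def cohort_to_frame(cohort: Cohort) -> pd.DataFrame:
    """Flatten a cohort to the long trial-log layout."""
    rows = [
        {
            "participant_id": s.participant_id,
            "block": t.block,
            "trial": t.index_in_block,
            "player_item": t.player.char,
            "computer_item": t.computer.char,
            "outcome": t.outcome.value,
        }
        for s in cohort
        for t in s.trials
    ]
    return pd.DataFrame(rows, columns=TRIAL_LOG_COLUMNS)


def write_trial_log(cohort: Cohort, path: str | Path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)


def read_trial_log(path: str | Path) -> Cohort:
    """Read and validate a trial-log CSV into a Cohort.

    Rows are grouped by participant and block and ordered by trial number.
    An outcome column inconsistent with the two items, or a gap in the
    1-based trial numbering within a block, raises naming the first bad row
    (1-based data row numbers, header excluded).
    """
    frame = pd.read_csv(path, dtype={"participant_id": str})
    missing = [c for c in TRIAL_LOG_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"trial log {path}: missing columns {missing}")
    frame["source_row"] = range(1, len(frame) + 1)
    frame = frame.sort_values(["participant_id", "block", "trial"], kind="stable")

    sessions = []
    for pid, sub in frame.groupby("participant_id", sort=False):
        trials = []
        for rec in sub.itertuples(index=False):
            player = Item.from_label(rec.player_item)
            computer = Item.from_label(rec.computer_item)
            stated = Outcome.from_label(rec.outcome)
            expected = resolve_outcome(player, computer)
            if stated is not expected:
                raise ValueError(
                    f"trial log {path} row {rec.source_row}: outcome {stated.value!r} "
                    f"inconsistent with items {player.name} vs {computer.name} "
                    f"(expected {expected.value!r})"
                )
            trials.append(Trial(int(rec.block), int(rec.trial), player, computer, expected))
        try:
            sessions.append(Session(participant_id=str(pid), trials=trials))
        except ValueError as err:
            raise ValueError(f"trial log {path}: {err}") from None
    return Cohort(sessions=sessions)


# ---------------------------------------------------------------------------
# Run configuration and pipeline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs, recorded verbatim in the manifest."""

    n_participants: int = 31
    n_blocks: int = 3
    block_length: int = 75
    preset: str = "paper-like"
    theta: tuple[float, ...] | None = None  # row-major 9-vector override
    kappa: float | None = None
    concentration: float | None = 200.0
    seed: int | None = None
    alpha: float = 0.05
    transform: str = "raw"  # raw | arcsine | both
    input_log: str | None = None  # analyse this log instead of simulating

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.transform not in ("raw", "arcsine", "both"):
            raise ValueError("transform must be raw, arcsine or both")
        if self.input_log is None and self.seed is None:
            raise ValueError("a seed is mandatory for simulation runs")
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; choose from {sorted(PRESETS)}")

    def policy(self) -> SwitchPolicy:
        base = PRESETS[self.preset]
        mapping = base.to_mapping()
        if self.theta is not None:
            if len(self.theta) != 9:
                raise ValueError("theta override must have 9 row-major entries")
            mapping["theta"] = list(self.theta)
        if self.kappa is not None:
            mapping["kappa"] = self.kappa
        return SwitchPolicy.from_mapping(mapping)

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(
            n_participants=self.n_participants,
            n_blocks=self.n_blocks,
            block_length=self.block_length,
            policy=self.policy(),
            concentration=self.concentration,
            seed=self.seed,
        )


def _anova_suite(cohort: Cohort, transform: bool, alpha: float):
    """All ANOVAs and Tukey decompositions of one analysis pass."""
    n_subj = len(cohort)
    results = []

    item_pct = cohort_marginal_array(cohort, "item")
    outcome_pct = cohort_marginal_array(cohort, "outcome")
    res_item = rm_anova_oneway(item_pct, "item at n")
    res_outcome = rm_anova_oneway(outcome_pct, "outcome at n")
    results += [("marginal", res_item), ("marginal", res_outcome)]

    fo, _ = cohort_first_order_array(cohort, transform=transform)
    fo_results = rm_anova(fo, ["item at n", "outcome at n", "strategy at n+1"])
    results += [("first-order", r) for r in fo_results]

    so, _ = cohort_second_order_array(cohort, transform=transform)
    so_results = rm_anova(so, ["strategy at n+1", "strategy at n+2"])
    results += [("second-order", r) for r in so_results]

    # Tukey decomposition of the outcome x strategy and strategy x strategy
    # interactions: simple effects of strategy at fixed conditioning level,
    # tested against the interaction's own error term with n = subjects.
    strategy_labels = [s.value for s in STRATEGIES]
    tukey_rows: list[pd.DataFrame] = []

    def decompose(label, levels, means_by_level, inter):
        # A zero error term (e.g. every participant perfectly deterministic)
        # leaves nothing to studentize against; skip that decomposition.
        if inter.mse <= 0:
            logger.warning("skipping Tukey decomposition %r: zero error term", label)
            return
        for at, means in zip(levels, means_by_level):
            res = tukey_hsd(means, inter.mse, inter.df_den, n_subj, alpha, strategy_labels)
            tukey_rows.append(res.pairs.assign(decomposition=label, at=at))

    inter_os = next(r for r in fo_results if r.effect == "outcome at n x strategy at n+1")
    decompose(
        "outcome x strategy", [o.value for o in OUTCOMES], fo.mean(axis=(0, 1)), inter_os
    )
    inter_ss = next(r for r in so_results if r.effect == "strategy at n+1 x strategy at n+2")
    decompose(
        "strategy x strategy", strategy_labels, so.mean(axis=0), inter_ss
    )
    if not tukey_rows:
        tukey_rows.append(pd.DataFrame(columns=[
            "level_a", "level_b", "mean_a", "mean_b", "diff", "q", "p",
            "significant", "decomposition", "at",
        ]))

    table = anova_table([r for _, r in results])
    table.insert(0, "analysis", [a for a, _ in results])
    return table, pd.concat(tukey_rows, ignore_index=True)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Simulate (or load) a cohort and write every analysis artifact.

    Emits trial_log.csv, marginal.csv, first_order.csv, second_order.csv,
    computer_response.csv, anova.csv, tukey.csv and manifest.json to
    ``out_dir``; returns the manifest dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "load"
    try:
        if config.input_log is not None:
            cohort = read_trial_log(config.input_log)
            logger.info("loaded %d sessions from %s", len(cohort), config.input_log)
        else:
            stage = "simulate"
            cohort = generate_cohort(config.cohort_config())
            logger.info(
                "simulated %d participants x %d blocks x %d trials (preset %s, seed %s)",
                config.n_participants, config.n_blocks, config.block_length,
                config.preset, config.seed,
            )
        write_trial_log(cohort, out / "trial_log.csv")

        stage = "descriptives"
        per_marginal = [marginal_counts(s) for s in cohort]
        per_first = [first_order_table(s) for s in cohort]
        per_second = [second_order_table(s) for s in cohort]
        per_computer = [computer_response_table(s) for s in cohort]
        for s in cohort:
            logger.info(
                "participant %s: %d trials, %d first-order transitions, "
                "%d second-order pairs retained",
                s.participant_id, s.n_trials,
                n_first_order_transitions(s), n_second_order_pairs(s),
            )
        pd.concat(per_marginal, ignore_index=True).to_csv(out / "marginal.csv", index=False)
        pd.concat(per_first, ignore_index=True).to_csv(out / "first_order.csv", index=False)
        pd.concat(per_second, ignore_index=True).to_csv(out / "second_order.csv", index=False)
        pd.concat(per_computer, ignore_index=True).to_csv(
            out / "computer_response.csv", index=False
        )

        stage = "inference"
        passes = {"raw": [False], "arcsine": [True], "both": [False, True]}[config.transform]
        anova_frames, tukey_frames = [], []
        for transformed in passes:
            label = "arcsine" if transformed else "raw"
            a_tab, t_tab = _anova_suite(cohort, transformed, config.alpha)
            anova_frames.append(a_tab.assign(scale=label))
            tukey_frames.append(t_tab.assign(scale=label))
        pd.concat(anova_frames, ignore_index=True).to_csv(out / "anova.csv", index=False)
        pd.concat(tukey_frames, ignore_index=True).to_csv(out / "tukey.csv", index=False)

        stage = "manifest"
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "preset": config.preset,
            "policy": config.policy().to_mapping() if config.input_log is None else None,
            "concentration": config.concentration,
            "n_participants": config.n_participants,
            "n_blocks": config.n_blocks,
            "block_length": config.block_length,
            "alpha": config.alpha,
            "transform": config.transform,
            "input_log": config.input_log,
            "zero_proportion_reading": ZERO_PROPORTION_READING,
            "artifacts": [
                "trial_log.csv", "marginal.csv", "first_order.csv",
                "second_order.csv", "computer_response.csv", "anova.csv", "tukey.csv",
            ],
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        return manifest
    except Exception:
        logger.error("pipeline stage %r failed", stage)
        raise


def aggregate_artifacts(out_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Cohort-mean summaries of the per-participant tables in an output dir."""
    out = Path(out_dir)
    first = pd.read_csv(out / "first_order.csv")
    second = pd.read_csv(out / "second_order.csv")
    comp = pd.read_csv(out / "computer_response.csv")
    per = lambda df: [g for _, g in df.groupby("participant", sort=False)]
    return {
        "first_order": aggregate_cohort(per(first), ["item", "outcome", "strategy"]),
        "second_order": aggregate_cohort(per(second), ["strategy_n1", "strategy_n2"]),
        "computer_response": aggregate_cohort(per(comp), ["computer_item", "player_next"]),
    }
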