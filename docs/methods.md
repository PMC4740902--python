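# Methods

## Game encoding

Items carry fixed indices Rock=0, Paper=1, Scissors=2, chosen so that the
cyclic "beats" relation is +1 (mod 3). One modular difference then serves
double duty: `(player − computer) mod 3` ∈ {0,1,2} resolves a trial to
{draw, win, lose}, and `(next − prev) mod 3` classifies the player's own
transition to {stay, upgrade, downgrade}. *Upgrade* means playing the item
that would have beaten your previous item; *downgrade* the item it would
have beaten. Outcomes are always expressed from the participant's
perspective. In files, items are single characters R/P/S; full words are
accepted case-insensitively on input.

## The computer opponent

The study design's opponent is a **balanced schedule**: each 75-trial
block is a uniform random permutation of a multiset holding each item
exactly 25 times, so the opponent plays the mixed-strategy equilibrium
with *exact* per-block counts rather than in expectation. Blocks are
shuffled independently and the shuffle is unconstrained (no run-length
limits — nothing in the design suggests any). An i.i.d. uniform agent is
available for comparison; the two are indistinguishable to any opponent's
expected outcome distribution but only the schedule gives exact counts.

## The behavioural model (switch agent)

A participant is modelled by a `SwitchPolicy`:

- `theta` — a 3×3 row-stochastic table P(strategy at *n*+1 | outcome at
  *n*), rows (win, lose, draw), columns (stay, upgrade, downgrade); rows
  must sum to 1 within 1e-9.
- `kappa` ∈ [0,1] — *momentum*: the probability of repeating the previous
  transition's strategy instead of sampling from `theta`. Momentum applies
  only when the previous move was upgrade or downgrade, because the
  second-order regularity to be emulated is that the two cyclic moves
  perpetuate themselves while staying does not.
- `pi0` — the item distribution for history-free trials (the first trial
  of each block); default uniform. Inter-trial history never crosses a
  block boundary.

Presets:

| preset | theta (win / lose / draw) | kappa |
| --- | --- | --- |
| `paper-like` | (.40,.30,.30) / (.24,.34,.42) / (.26,.44,.30) | 0.15 |
| `wsls-deterministic` | (1,0,0) / (0,0,1) / (0,1,0) | 0 |
| `uniform` | all rows (1/3,1/3,1/3) | 0 |

The `paper-like` constants are **synthetic**: the regularities they encode
are qualitative (win→stay modal; lose→switch, downgrade modal, stay
minimal; draw→switch, upgrade modal, stay minimal; positive momentum), and
the magnitudes are package choices sized to give clearly detectable but
not saturated effects at 31 participants. No claim is made that they
match any human effect sizes. `wsls-deterministic` is the degenerate
limit; it provably implies the emergent rule *computer plays Scissors at
n ⟹ participant plays Rock at n+1* (win with Rock → stay on Rock; loss
with Paper → downgrade to Rock; draw with Scissors → upgrade to Rock).

## The synthetic cohort

`CohortConfig` defaults reproduce the study dimensions: 31 participants ×
3 blocks × 75 trials (6975 trials). Between-participant heterogeneity
jitters each theta row *r* as Dirichlet(c·r) with concentration c
(default 200, giving per-entry SD ≈ 0.03 — a deliberate, undocumented-by-
any-source choice, since no per-cell variance is available to calibrate
against; c = None/∞ shares theta exactly). Rows containing zeros pass
through unchanged (Dirichlet parameters must be positive). Participant
outcomes are always *computed* from the two chosen items, never sampled.

What the generator does **not** emulate: learning or fatigue across
blocks, reaction times, item-specific (rather than outcome-specific)
biases beyond what theta induces, and any adaptation to the opponent.
Passing tests therefore show the pipeline recovers the structure this
generator puts in; they are silent on how well the model fits real play.

## Tables and trial accounting

All transition tables use within-block consecutive trials only, so the
default design yields 225 − 3 = 222 first-order transitions and
225 − 6 = 219 second-order pairs per participant (generally
total − n_blocks and total − 2·n_blocks). Tables are cell-normalised
conditional proportions; a nonempty cell's three proportions sum to 1,
which makes the conditioning factors' main effects in the downstream
ANOVAs exactly vacuous (F = 0, p = 1) — retained deliberately as a
structural check. Empty cells are reported as missing (NaN, denominator
0), never as zero; cohort aggregation averages each cell over the
participants that possess it and reports that count.

The arc-sine transform is 2·asin(√x) for x > 0. For x = 0 the printed
form of the zero-cell correction is ambiguous between 1/(2y) and (1/2)·y;
this package reads it as **1/(2y)** — the standard Bartlett small-sample
correction, and the only reading that keeps the argument in [0,1] — and
records the reading in every run manifest.

## Repeated-measures ANOVA

The design is balanced and fully within-subjects with one observation per
subject per cell, so every term's SS is computed exactly by Möbius
inclusion-exclusion over marginal means (equivalently, the classical
subjects-by-treatment decomposition). Effect E is tested against its own
subject×E interaction: F = MS_E / MS_{E×S}, df = (∏(levels−1),
∏(levels−1)·(N−1)); η²ₚ = SS_E/(SS_E+SS_{E×S}). SS values below 1e-12 of
the total SS are snapped to exact zero so that structurally null effects
report F = 0, p = 1 rather than a ratio of rounding noise (η²ₚ is NaN
when both SS vanish). Missing cells are a hard error listing the empty
cells; no imputation.

No sphericity correction is applied by default — the uncorrected integer
dfs are the quantities of record. `correction="gg"` applies
Greenhouse–Geisser via orthonormal effect contrasts (Kronecker products of
per-factor Helmert bases and averaging vectors), ε = tr(CSC′)²/(d·tr((CSC′)²)),
clamped to [1/d, 1]; it rescales both dfs and leaves F unchanged.

Tukey HSD takes explicit cell means, an error term, its df, and n per
mean: qᵢⱼ = |m̄ᵢ−m̄ⱼ|/√(MS_error/n), compared with the studentized-range
quantile q(α; k, df). For interaction decomposition the pipeline's
convention — fixed here because within-subjects HSD has no single
standard — is simple effects of strategy at each level of the other
factor, tested against the interaction's own error term with n = number
of subjects. Decompositions with a zero error term (possible under
deterministic presets, where all participants behave identically) are
skipped with a warning rather than fabricating infinite q values.

Analyses run on raw proportions by default; `--transform arcsine` or
`both` re-runs the same suite on transformed values. Marginal-frequency
ANOVAs use the percentage scale (F, p and η²ₚ are invariant to this;
only MSE's units change).

## Pipeline and reproducibility

`run_pipeline` writes seven artifacts (trial log, four descriptive
tables, ANOVA table, Tukey table) plus `manifest.json` recording the
seed, preset constants, jitter concentration, alpha, transform choice and
the zero-proportion reading, so any run is reproducible from its
manifest. All randomness flows from one `numpy` Generator per run; equal
configs and seeds give byte-identical artifacts. INFO logging announces
the per-participant 222/219 trial accounting.

`scripts/acceptance.py` recomputes the headline quantities at sizes
chosen to keep the whole run under a few seconds: single sessions for the
design accounting, 31×225 cohorts for recovery and the emergent rule,
1000 trials for exploiter dominance, and 2000 simulated null datasets
(31×3, subject effects plus within-subject label shuffling) for the
type-I error of the one-way rm-ANOVA.

## Known limitations

- The generative model conditions only on the previous outcome and move;
  real players also track opponent items, longer histories, and scores.
- Heterogeneity is a single Dirichlet concentration; real cohorts likely
  mix qualitatively different strategies.
- Tukey p-values for within-subject simple effects are approximate in the
  usual sense that sphericity of the interaction error term is assumed.
- Only the 3-item cycle is supported; n-item generalisations
  (Rock-Paper-Scissors-Lizard-Spock) are out of scope.
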