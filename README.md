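# rpslab

Simulation and inter-trial analysis of iterated Rock-Paper-Scissors (RPS)
played against a mixed-strategy-equilibrium computer opponent.

RPS is a non-transitive game — Rock beats Scissors, Paper beats Rock,
Scissors beats Paper — so the unique Nash equilibrium is to play each item
with probability 1/3, and any systematic deviation is exploitable. Human
players nevertheless show lawful regularities: a mild bias toward Rock, a
generalised *win-stay lose-shift* rule, and two distinct kinds of switch —
**upgrade** (play the item that would have beaten your last one, e.g.
Rock→Paper) and **downgrade** (play the item your last one would have
beaten, e.g. Rock→Scissors). Losses tend to prompt downgrades, draws
upgrades, and both cyclic moves tend to be repeated across consecutive
trials. `rpslab` is for researchers in behavioural game theory and
cognitive decision science who want to simulate this experimental design,
generate realistic trial logs, and run the full inter-trial analysis.

## What it computes

For each participant × block × trial log (default design: 31 participants,
3 blocks of 75 trials, computer playing each item exactly 25 times per
block in random order):

- **Marginal tables** — item and outcome frequencies at trial *n*.
- **First-order table** — P(strategy at *n*+1 | item at *n*, outcome at
  *n*), where strategy ∈ {stay, upgrade, downgrade} classifies the
  player's own transition. Within-block transitions only: 3×75 trials give
  exactly 222 transitions.
- **Second-order table** — P(strategy at *n*+2 | strategy at *n*+1); 219
  transition pairs.
- **Computer-response table** — P(player item at *n*+1 | computer item at
  *n*), which exposes the emergent rule that deterministic
  win-stay/lose-downgrade/draw-upgrade play always answers the computer's
  Scissors with Rock.
- **Repeated-measures ANOVA** with per-effect subject-by-effect error
  terms: F = MS_effect/MS_error with df = (∏(levels−1), ∏(levels−1)·(N−1)),
  partial eta squared η²ₚ = SS_effect/(SS_effect+SS_error), optional
  Greenhouse–Geisser correction, and Tukey HSD decomposition via the
  studentized range q = |m̄ᵢ−m̄ⱼ|/√(MS_error/N).
- **Arc-sine transform** 2·asin(√x) of proportions (zero cells use the
  small-sample correction x → 1/(2y) for a cell with y possible
  observations), available alongside the raw-proportion analysis.

Because conditional proportions within a cell sum to 1, the conditioning
factors' main effects are exactly vacuous (F = 0, p = 1) — a built-in
sanity check the pipeline reproduces.

## Worked example

```sh
rpslab analyze --seed 1 --simulate-first --out demo
rpslab report demo
```

prints (abridged):

```
run: preset=paper-like seed=1 participants=31
scale     analysis                          effect       F  df_num  df_den    MSE      p  eta_p2
  raw     marginal                       item at n  0.3220     2.0    60.0 11.654 0.7259  0.0106
  raw  first-order                 strategy at n+1 50.7961     2.0    60.0  0.018 0.0000  0.6287
  raw  first-order  outcome at n x strategy at n+1 72.5231     4.0   120.0  0.014 0.0000  0.7074
  raw second-order strategy at n+1 x strategy at n+2 32.9655   4.0   120.0  0.005 0.0000  0.5235
...
  [outcome x strategy @ lose] stay vs downgrade: diff=-0.251 q=11.78
  [outcome x strategy @ draw] stay vs upgrade: diff=-0.240 q=11.24
```

Reading: the simulated cohort plays all three items at statistically
indistinguishable rates (item at *n*: F(2,60)=0.32, p=0.73), but strategy
at *n*+1 depends strongly on the previous outcome
(outcome×strategy: F(4,120)=72.5, η²ₚ=0.71): after a loss, staying is far
less likely than downgrading (Tukey diff −0.251, q=11.8), and after a draw
less likely than upgrading — the generalised win-stay lose-shift pattern
the generator encodes. The second-order interaction (F(4,120)=33.0) shows
upgrade and downgrade moves perpetuating themselves.

The same pipeline runs on real logs: `rpslab analyze --log trials.csv
--out results --seed 0` accepts any CSV with columns
`participant_id,block,trial,player_item,computer_item,outcome` (items
R/P/S or full words; the outcome column is validated against the game
rule on read).

## Layout

| module | contents |
| --- | --- |
| `rpslab.core` | items, outcomes, stay/upgrade/downgrade classification, trials, sessions |
| `rpslab.agents` | balanced-schedule opponent, outcome-conditioned switch agents, adaptive exploiter, match harness |
| `rpslab.synth` | presets and the synthetic cohort generator |
| `rpslab.tables` | marginal / first-order / second-order / computer-response tables, arc-sine transform |
| `rpslab.anova` | repeated-measures ANOVA, partial eta squared, Tukey HSD |
| `rpslab.io` | trial-log CSV round trip, run configuration, pipeline, manifest |
| `rpslab.cli` | `rpslab simulate / analyze / report` |

See `docs/methods.md` for the behavioural model, its parameters, and the
numerical conventions.
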