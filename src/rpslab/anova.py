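"""Within-subjects inferential machinery: repeated-measures ANOVA with
per-effect error terms, partial eta squared, and Tukey HSD decomposition.

The design is fully within-subjects and balanced with one observation per
subject-by-cell, so every effect's sum of squares has the classical
closed form.  The SS of any term (any subset of the subject and treatment
factors) is computed by Möbius inclusion-exclusion over marginal means:
the term's component at each cell is the alternating sum of means over
all subsets of its axes, and the SS is the squared component summed over
the full grid.  Each treatment effect E is tested against its own
subject-by-E interaction (MS ratio), giving the familiar
df_num = prod(levels-1), df_den = df_num * (n_subjects - 1).

No sphericity correction is applied by default (matching integer printed
dfs); a Greenhouse-Geisser correction via orthonormal effect contrasts is
available behind a flag for main effects and interactions alike.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import chain, combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

# ---------------------------------------------------------------------------
# Results containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnovaResult:
    """One tested effect of a repeated-measures ANOVA."""

    effect: str
    F: float
    df_num: float
    df_den: float
    ss_effect: float
    ss_error: float
    mse: float
    p: float
    eta_p2: float

    def as_dict(self) -> dict:
        return {
            "effect": self.effect,
            "F": self.F,
            "df_num": self.df_num,
            "df_den": self.df_den,
            "ss_effect": self.ss_effect,
            "ss_error": self.ss_error,
            "MSE": self.mse,
            "p": self.p,
            "eta_p2": self.eta_p2,
        }


@dataclass(frozen=True)
class TukeyResult:
    """All-pairs studentized-range comparison at a fixed family-wise alpha."""

    level_names: tuple[str, ...]
    means: tuple[float, ...]
    ms_error: float
    df_error: float
    n_per_mean: int
    alpha: float
    q_critical: float
    pairs: pd.DataFrame  # columns: level_a, level_b, mean_a, mean_b, diff, q, p, significant


def partial_eta_squared(ss_effect: float, ss_error: float) -> float:
    """Effect size SS_effect / (SS_effect + SS_error); NaN when both are 0."""
    if ss_effect < 0 or ss_error < 0:
        raise ValueError("sums of squares must be nonnegative")
    denom = ss_effect + ss_error
    if denom == 0:
        return float("nan")
    return ss_effect / denom


# ---------------------------------------------------------------------------
# Sums of squares by inclusion-exclusion
# ---------------------------------------------------------------------------


def _subsets(axes: tuple[int, ...]):
    return chain.from_iterable(combinations(axes, r) for r in range(len(axes) + 1))


def term_ss(y: np.ndarray, term_axes: Sequence[int]) -> float:
    """SS of the ANOVA term spanned by ``term_axes`` of a balanced array.

    The component of the term at each cell is
    sum over U subseteq T of (-1)^(|T|-|U|) * mean over axes outside U,
    broadcast back to the full grid; the SS is the sum of its squares.
    """
    term = tuple(sorted(term_axes))
    all_axes = tuple(range(y.ndim))
    comp = np.zeros_like(y, dtype=float)
    for kept in _subsets(term):
        reduce_over = tuple(ax for ax in all_axes if ax not in kept)
        sign = (-1) ** (len(term) - len(kept))
        if reduce_over:
            comp = comp + sign * y.mean(axis=reduce_over, keepdims=True)
        else:
            comp = comp + sign * y
    return float((comp**2).sum())


def _gg_epsilon(y: np.ndarray, effect_axes: tuple[int, ...]) -> float:
    """Greenhouse-Geisser epsilon for one effect via orthonormal contrasts.

    Builds the effect's contrast matrix as a Kronecker product (Helmert
    contrasts on effect factors, the averaging vector on the rest), applies
    it to the per-subject flattened cell vectors, and evaluates
    epsilon = tr(S)^2 / (d * tr(S^2)) on the contrast covariance S.
    """
    n_subj = y.shape[0]
    mats = []
    for ax in range(1, y.ndim):
        levels = y.shape[ax]
        if ax in effect_axes:
            # orthonormal Helmert-style contrasts: rows of an orthonormal
            # basis of the space orthogonal to the constant vector
            full, _ = np.linalg.qr(
                np.column_stack([np.ones(levels), np.eye(levels)[:, :-1]])
            )
            mats.append(full[:, 1:].T)
        else:
            mats.append(np.full((1, levels), 1.0 / levels))
    contrast = mats[0]
    for m in mats[1:]:
        contrast = np.kron(contrast, m)
    scores = y.reshape(n_subj, -1) @ contrast.T
    s = np.cov(scores, rowvar=False)
    s = np.atleast_2d(s)
    d = s.shape[0]
    tr = np.trace(s)
    denom = d * np.trace(s @ s)
    if denom == 0:
        return 1.0
    eps = tr**2 / denom
    return float(min(1.0, max(eps, 1.0 / d)))


def rm_anova(
    data: np.ndarray,
    factor_names: Sequence[str] | None = None,
    correction: str = "none",
) -> list[AnovaResult]:
    """Repeated-measures ANOVA of a balanced fully-within design.

    Parameters
    ----------
    data
        Array of shape (n_subjects, levels_1, ..., levels_k): one
        observation per subject per factorial cell.
    factor_names
        Names for the k treatment factors; defaults to A, B, C, ...
    correction
        "none" (default) or "gg" for Greenhouse-Geisser adjusted dfs and
        p values.

    Returns one :class:`AnovaResult` per main effect and interaction, each
    tested against its own subject-by-effect error term.
    """
    y = np.asarray(data, dtype=float)
    if y.ndim < 2:
        raise ValueError("data must be (n_subjects, levels...) with >=1 factor")
    if np.isnan(y).any():
        raise ValueError("missing cells are not supported; complete the layout first")
    n_subj = y.shape[0]
    if n_subj < 2:
        raise ValueError("need at least 2 subjects")
    if any(l < 2 for l in y.shape[1:]):
        raise ValueError("every factor needs at least 2 levels")
    if correction not in ("none", "gg"):
        raise ValueError("correction must be 'none' or 'gg'")

    k = y.ndim - 1
    if factor_names is None:
        factor_names = [chr(ord("A") + i) for i in range(k)]
    if len(factor_names) != k:
        raise ValueError(f"expected {k} factor names, got {len(factor_names)}")

    results: list[AnovaResult] = []
    factor_axes = tuple(range(1, y.ndim))
    # SS below this share of the total is numerical noise from the
    # inclusion-exclusion cancellation; snap it to an exact zero.
    ss_total = float(((y - y.mean()) ** 2).sum())
    tol = 1e-12 * max(ss_total, np.finfo(float).tiny)
    for r in range(1, k + 1):
        for effect_axes in combinations(factor_axes, r):
            ss_eff = term_ss(y, effect_axes)
            ss_err = term_ss(y, (0, *effect_axes))
            ss_eff = 0.0 if ss_eff < tol else ss_eff
            ss_err = 0.0 if ss_err < tol else ss_err
            df_num = float(np.prod([y.shape[ax] - 1 for ax in effect_axes]))
            df_den = df_num * (n_subj - 1)
            eps = 1.0
            if correction == "gg":
                eps = _gg_epsilon(y, effect_axes)
            ms_eff = ss_eff / df_num
            ms_err = ss_err / df_den
            f_stat = ms_eff / ms_err if ms_err > 0 else (0.0 if ss_eff == 0 else float("inf"))
            p = float(stats.f.sf(f_stat, df_num * eps, df_den * eps))
            name = " x ".join(factor_names[ax - 1] for ax in effect_axes)
            results.append(
                AnovaResult(
                    effect=name,
                    F=float(f_stat),
                    df_num=df_num * eps,
                    df_den=df_den * eps,
                    ss_effect=ss_eff,
                    ss_error=ss_err,
                    mse=ms_err,
                    p=p,
                    eta_p2=partial_eta_squared(ss_eff, ss_err),
                )
            )
    return results


def rm_anova_oneway(
    data: np.ndarray, factor_name: str = "level", correction: str = "none"
) -> AnovaResult:
    """One-way repeated-measures ANOVA on a (n_subjects, n_levels) table."""
    y = np.asarray(data, dtype=float)
    if y.ndim != 2:
        raise ValueError("one-way data must be a 2-D subjects x levels table")
    return rm_anova(y, [factor_name], correction=correction)[0]


def rm_anova_factorial(
    data: np.ndarray, factor_names: Sequence[str], correction: str = "none"
) -> list[AnovaResult]:
    """Factorial fully-within ANOVA; alias of :func:`rm_anova` with named factors."""
    return rm_anova(data, factor_names, correction=correction)


def anova_table(results: Sequence[AnovaResult]) -> pd.DataFrame:
    """Stack results into the tidy ANOVA table emitted by the pipeline."""
    return pd.DataFrame([r.as_dict() for r in results])


# ---------------------------------------------------------------------------
# Tukey HSD
# ---------------------------------------------------------------------------


def tukey_hsd(
    cell_means: Sequence[float],
    ms_error: float,
    df_error: float,
    n_per_mean: int,
    alpha: float = 0.05,
    level_names: Sequence[str] | None = None,
) -> TukeyResult:
    """All-pairs Tukey HSD using a supplied error term.

    q_ij = |mean_i - mean_j| / sqrt(ms_error / n_per_mean), compared with
    the studentized-range critical value q(alpha; k, df_error).  Supplying
    the effect's own subject-by-effect MS error makes this the
    within-subjects decomposition used after a significant rm-ANOVA effect.
    """
    means = np.asarray(cell_means, dtype=float)
    k = means.size
    if k < 2:
        raise ValueError("need at least 2 means")
    if ms_error <= 0:
        raise ValueError("ms_error must be positive")
    if df_error < 1:
        raise ValueError("df_error must be >= 1")
    if n_per_mean < 2:
        raise ValueError("n_per_mean must be >= 2")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if level_names is None:
        level_names = [f"level{i}" for i in range(k)]
    if len(level_names) != k:
        raise ValueError("level_names length must match cell_means")

    se = np.sqrt(ms_error / n_per_mean)
    q_crit = float(stats.studentized_range.ppf(1 - alpha, k, df_error))
    rows = []
    for i, j in combinations(range(k), 2):
        diff = means[i] - means[j]
        q = abs(diff) / se
        p = float(stats.studentized_range.sf(q, k, df_error))
        rows.append(
            {
                "level_a": level_names[i],
                "level_b": level_names[j],
                "mean_a": means[i],
                "mean_b": means[j],
                "diff": diff,
                "q": q,
                "p": p,
                "significant": bool(q > q_crit),
            }
        )
    return TukeyResult(
        level_names=tuple(level_names),
        means=tuple(means),
        ms_error=float(ms_error),
        df_error=float(df_error),
        n_per_mean=int(n_per_mean),
        alpha=float(alpha),
        q_critical=q_crit,
        pairs=pd.DataFrame(rows),
    )
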