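"""Behavioral statistics for the contextual avoidance task.

Covers the full behavioral battery of the study design: per-context
proportions of low-pain-probability choices, exact binomial tests against
chance, a paired t-test between contexts, a 2 (probability level) x 2
(context) repeated-measures ANOVA on reaction times, Pearson trait
correlations with a Bonferroni 0.05/7 threshold, and the effect-size /
power utilities used to justify the sample size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.anova import AnovaRM
from statsmodels.stats.power import TTestPower

from .task import Session

#: Bonferroni-corrected threshold for the seven trait scales.
BONFERRONI_7 = 0.05 / 7


class DegenerateDataError(ValueError):
    """Raised when a test's input has no variance to work with."""


@dataclass(frozen=True)
class StatResult:
    statistic: float
    df: float | tuple[float, float] | None
    pvalue: float
    test: str
    correction: str | None = None
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Choice summaries and tests
# ---------------------------------------------------------------------------

def summarize_choices(sessions: list[Session]) -> pd.DataFrame:
    """Per participant x context proportion of low-risk choices.

    The low-probability shape is defined per context by the session's own
    contingency map.
    """
    rows = []
    for sess in sessions:
        cfg = sess.config
        for ctx in cfg.contexts:
            low = cfg.low_risk_shape(ctx)
            trials = [tr for tr in sess.trials if tr.context == ctx]
            n = len(trials)
            k = sum(tr.action == low for tr in trials)
            rows.append(
                {
                    "participant": sess.participant,
                    "context": ctx,
                    "n_trials": n,
                    "n_low": k,
                    "prop_low": k / n if n else np.nan,
                }
            )
    return pd.DataFrame(rows)


def binomial_vs_half(
    k: int, n: int, method: str = "minlike"
) -> StatResult:
    """Exact two-sided binomial test of k/n against 50%.

    ``minlike`` (default) sums all outcomes with pmf <= pmf(k);
    ``double`` doubles the smaller tail (capped at 1).  At p0 = 0.5 the two
    conventions coincide.
    """
    if n <= 0:
        raise DegenerateDataError("binomial test requires n >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, {n}]")
    if method == "minlike":
        p = sps.binomtest(k, n, p=0.5).pvalue
    elif method == "double":
        lower = sps.binom.cdf(k, n, 0.5)
        upper = sps.binom.sf(k - 1, n, 0.5)
        p = min(1.0, 2.0 * min(lower, upper))
    else:
        raise ValueError(f"unknown method {method!r}")
    return StatResult(
        statistic=k / n,
        df=None,
        pvalue=float(p),
        test=f"binomial-vs-0.5 ({method})",
        extra={"k": k, "n": n},
    )


def choice_binomials(
    summary: pd.DataFrame, pooled: bool = True
) -> pd.DataFrame:
    """Binomial tests of low-risk choice counts against chance.

    With ``pooled=True`` (the headline variant) counts are pooled over
    participants within each context; otherwise one test per participant
    and context.
    """
    rows = []
    if pooled:
        for ctx, grp in summary.groupby("context", sort=True):
            k = int(grp["n_low"].sum())
            n = int(grp["n_trials"].sum())
            res = binomial_vs_half(k, n)
            rows.append(
                {
                    "context": ctx,
                    "unit": "pooled",
                    "k": k,
                    "n": n,
                    "prop": k / n,
                    "pvalue": res.pvalue,
                }
            )
    else:
        for _, row in summary.iterrows():
            res = binomial_vs_half(int(row["n_low"]), int(row["n_trials"]))
            rows.append(
                {
                    "context": row["context"],
                    "unit": row["participant"],
                    "k": int(row["n_low"]),
                    "n": int(row["n_trials"]),
                    "prop": row["prop_low"],
                    "pvalue": res.pvalue,
                }
            )
    return pd.DataFrame(rows)


def paired_t(x, y) -> StatResult:
    """Classical paired t-test (two-sided), df = n - 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0):
        raise DegenerateDataError("differences have zero variance")
    t, p = sps.ttest_rel(x, y)
    return StatResult(
        statistic=float(t),
        df=x.size - 1,
        pvalue=float(p),
        test="paired-t",
    )


# ---------------------------------------------------------------------------
# Reaction-time ANOVA
# ---------------------------------------------------------------------------

def rt_cell_means(sessions: list[Session]) -> pd.DataFrame:
    """Long-format participant x probability x context RT cell means.

    A trial is "high" when the chosen shape is the high-pain-probability
    one in that trial's context.
    """
    rows = []
    for sess in sessions:
        cfg = sess.config
        for tr in sess.trials:
            level = (
                "high"
                if tr.action == cfg.high_risk_shape(tr.context)
                else "low"
            )
            rows.append(
                {
                    "participant": sess.participant,
                    "probability": level,
                    "context": tr.context,
                    "rt_ms": tr.rt_ms,
                }
            )
    long = pd.DataFrame(rows)
    return (
        long.groupby(["participant", "probability", "context"], sort=True)[
            "rt_ms"
        ]
        .mean()
        .reset_index()
    )


def rt_anova_2x2(cells: pd.DataFrame) -> dict[str, StatResult]:
    """2 x 2 repeated-measures ANOVA on RT cell means.

    ``cells`` must hold one row per participant x probability x context
    with columns participant, probability, context, rt_ms.  Returns F tests
    (df 1, n-1) for the two main effects and the interaction.
    """
    required = {"participant", "probability", "context", "rt_ms"}
    if not required.issubset(cells.columns):
        raise ValueError(f"cells table needs columns {sorted(required)}")
    counts = cells.groupby("participant").size()
    if (counts != 4).any():
        bad = counts[counts != 4].index.tolist()
        raise ValueError(f"incomplete 2x2 cells for participants {bad}")
    per_subject_var = cells.groupby("participant")["rt_ms"].var(ddof=0)
    if np.allclose(per_subject_var, 0.0):
        # no variance between conditions for any subject: all effects null
        return {
            key: StatResult(
                statistic=0.0, df=(1.0, float(len(counts) - 1)),
                pvalue=1.0, test="rm-anova-2x2",
            )
            for key in ("probability", "context", "interaction")
        }
    aov = AnovaRM(
        cells,
        depvar="rt_ms",
        subject="participant",
        within=["probability", "context"],
    ).fit()
    tbl = aov.anova_table
    out = {}
    for key, row_name in [
        ("probability", "probability"),
        ("context", "context"),
        ("interaction", "probability:context"),
    ]:
        row = tbl.loc[row_name]
        out[key] = StatResult(
            statistic=float(row["F Value"]),
            df=(float(row["Num DF"]), float(row["Den DF"])),
            pvalue=float(row["Pr > F"]),
            test="rm-anova-2x2",
        )
    return out


# ---------------------------------------------------------------------------
# Trait correlations and power
# ---------------------------------------------------------------------------

def trait_correlations(
    effect: pd.Series, traits: pd.DataFrame, n_scales: int | None = None
) -> pd.DataFrame:
    """Pearson correlations of a per-participant effect with trait scales.

    Applies a Bonferroni threshold of 0.05 / n_scales (default: the number
    of trait columns, 7 for the temperament/character inventory).
    """
    common = effect.index.intersection(traits.index)
    if len(common) < 3:
        raise ValueError("need at least 3 participants with both measures")
    x = effect.loc[common].to_numpy(dtype=float)
    if np.allclose(x.std(), 0.0):
        raise DegenerateDataError("effect vector has zero variance")
    n_scales = n_scales or traits.shape[1]
    threshold = 0.05 / n_scales
    rows = []
    for scale in traits.columns:
        y = traits.loc[common, scale].to_numpy(dtype=float)
        if np.allclose(y.std(), 0.0):
            raise DegenerateDataError(f"trait {scale!r} has zero variance")
        r, p = sps.pearsonr(x, y)
        rows.append(
            {
                "scale": scale,
                "n": len(common),
                "r": float(r),
                "pvalue": float(p),
                "threshold": threshold,
                "significant": bool(p < threshold),
            }
        )
    return pd.DataFrame(rows)


def mean_effect_size(d1: float, d2: float) -> float:
    """Arithmetic mean of two Cohen's d effect sizes."""
    return (d1 + d2) / 2.0


def required_n(
    d: float,
    power: float = 0.8,
    alpha: float = 0.05,
    alternative: str = "two-sided",
) -> int:
    """Smallest n whose one-sample t-test power reaches the target.

    Exact noncentral-t power at each candidate n, scanned upward.
    ``alternative`` is "two-sided" or "larger" (one-sided).
    """
    if d <= 0:
        raise ValueError("effect size must be positive")
    if not 0 < power < 1:
        raise ValueError("power must lie in (0, 1)")
    solver = TTestPower()
    for n in range(2, 10_000):
        achieved = solver.power(
            effect_size=d, nobs=n, alpha=alpha, alternative=alternative
        )
        if achieved >= power:
            return n
    raise RuntimeError("no n below 10,000 reaches the requested power")


def achieved_power(
    d: float, n: int, alpha: float = 0.05, alternative: str = "two-sided"
) -> float:
    """One-sample t-test power at the given effect size and n."""
    return float(
        TTestPower().power(
            effect_size=d, nobs=n, alpha=alpha, alternative=alternative
        )
    )


# ---------------------------------------------------------------------------
# Report assembly (pipeline surface)
# ---------------------------------------------------------------------------

def behavior_report(
    sessions: list[Session],
) -> tuple[pd.DataFrame, dict[str, StatResult], str]:
    """Run the behavioral battery on a cohort.

    Returns the choice-summary table, the named test results, and a short
    human-readable text summary.
    """
    summary = summarize_choices(sessions)
    wide = summary.pivot(
        index="participant", columns="context", values="prop_low"
    )
    results: dict[str, StatResult] = {}
    contexts = list(wide.columns)
    if len(contexts) == 2 and len(wide) >= 2:
        try:
            results["paired_t_contexts"] = paired_t(
                wide[contexts[0]], wide[contexts[1]]
            )
        except DegenerateDataError:
            pass
    pooled = choice_binomials(summary, pooled=True)
    for _, row in pooled.iterrows():
        results[f"binomial_{row['context']}"] = StatResult(
            statistic=row["prop"],
            df=None,
            pvalue=row["pvalue"],
            test="binomial-vs-0.5 (pooled)",
            extra={"k": row["k"], "n": row["n"]},
        )
    cells = rt_cell_means(sessions)
    if cells.groupby("participant").size().eq(4).all() and len(
        cells["participant"].unique()
    ) >= 2:
        try:
            for key, res in rt_anova_2x2(cells).items():
                results[f"rt_anova_{key}"] = res
        except (ValueError, DegenerateDataError):
            pass
    lines = ["Behavioral summary", "=================="]
    mean_props = summary.groupby("context")["prop_low"].mean()
    for ctx, m in mean_props.items():
        lines.append(
            f"mean proportion of low-probability choices, context {ctx}: "
            f"{100 * m:.1f}%"
        )
    for name, res in results.items():
        df = "" if res.df is None else f", df={res.df}"
        lines.append(
            f"{name}: {res.test} statistic={res.statistic:.4g}{df}, "
            f"p={res.pvalue:.4g}"
        )
    return summary, results, "\n".join(lines)
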