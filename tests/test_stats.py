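"""Behavioral statistics: choice tests, RT ANOVA, trait correlations, power."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ctxlearn import (
    AgentParams,
    BONFERRONI_7,
    TaskConfig,
    binomial_vs_half,
    mean_effect_size,
    paired_t,
    required_n,
    rt_anova_2x2,
    simulate_session,
    summarize_choices,
    trait_correlations,
)
from ctxlearn.stats import (
    DegenerateDataError,
    achieved_power,
    choice_binomials,
    rt_cell_means,
)


def binomial_enumeration_oracle(k: int, n: int) -> float:
    """Two-sided exact p by direct pmf enumeration (minlike convention)."""
    pmf = [math.comb(n, i) * 0.5**n for i in range(n + 1)]
    return sum(p for p in pmf if p <= pmf[k] * (1 + 1e-12))


class TestChoiceSummaries:
    def test_counting_on_handbuilt_session(self):
        # four context-A trials choosing low, low, high, low -> 0.75
        cfg = TaskConfig(n_trials=4, context_balance={"A": 4, "B": 0})
        s = simulate_session(cfg, AgentParams(0.5, -1.0), 0)
        import dataclasses

        seq = ["square", "square", "rhombus", "square"]  # A: square is low
        trials = [
            dataclasses.replace(tr, action=a, context="A")
            for tr, a in zip(s.trials, seq)
        ]
        s = dataclasses.replace(s, trials=trials)
        summary = summarize_choices([s])
        row = summary[summary["context"] == "A"].iloc[0]
        assert row["prop_low"] == pytest.approx(0.75)

    def test_random_agent_near_half(self):
        sessions = [
            simulate_session(TaskConfig(), AgentParams(0.5, 0.0), seed)
            for seed in range(40)
        ]
        summary = summarize_choices(sessions)
        assert summary["prop_low"].mean() == pytest.approx(0.5, abs=0.05)

    def test_pooled_and_per_participant_units(self):
        sessions = [
            simulate_session(TaskConfig(), AgentParams(0.3, -3.0), seed)
            for seed in range(3)
        ]
        summary = summarize_choices(sessions)
        pooled = choice_binomials(summary, pooled=True)
        assert len(pooled) == 2 and (pooled["n"] == 90).all()
        per = choice_binomials(summary, pooled=False)
        assert len(per) == 6 and (per["n"] == 30).all()


class TestBinomial:
    def test_null_value_gives_p_one(self):
        assert binomial_vs_half(30, 60).pvalue == pytest.approx(1.0)

    def test_extreme_value_tail(self):
        # all 60 low-risk choices: p = 2 * 2^-60 = 2^-59
        assert binomial_vs_half(60, 60).pvalue == pytest.approx(
            2.0**-59, rel=1e-9
        )

    @pytest.mark.parametrize("n", [1, 7, 30, 60])
    def test_matches_enumeration_oracle(self, n):
        for k in range(n + 1):
            assert binomial_vs_half(k, n).pvalue == pytest.approx(
                binomial_enumeration_oracle(k, n), rel=1e-9
            )

    def test_symmetry(self):
        for k, n in [(5, 30), (12, 60), (0, 9)]:
            assert binomial_vs_half(k, n).pvalue == pytest.approx(
                binomial_vs_half(n - k, n).pvalue, rel=1e-12
            )

    def test_doubling_convention_agrees_at_half(self):
        for k, n in [(40, 60), (3, 10)]:
            assert binomial_vs_half(k, n, "double").pvalue == pytest.approx(
                binomial_vs_half(k, n, "minlike").pvalue, rel=1e-9
            )

    def test_zero_trials_rejected(self):
        with pytest.raises(DegenerateDataError):
            binomial_vs_half(0, 0)


class TestPairedT:
    def test_hand_computed_example(self):
        res = paired_t([0.5, 0.8], [0.4, 0.5])  # differences 0.1, 0.3
        assert res.statistic == pytest.approx(2.0, abs=1e-12)
        assert res.df == 1

    def test_zero_variance_differences_rejected(self):
        with pytest.raises(DegenerateDataError):
            paired_t([1.0, 2.0, 3.0], [0.5, 1.5, 2.5])

    def test_equals_one_sample_t_on_differences(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        res = paired_t(x, y)
        t, p = sps.ttest_1samp(x - y, 0.0)
        assert res.statistic == pytest.approx(float(t), abs=1e-12)
        assert res.pvalue == pytest.approx(float(p), abs=1e-12)

    def test_type_one_error_calibrated(self):
        # null simulation: rejection rate at alpha=.05 within [0.044, 0.056]
        rng = np.random.default_rng(314)
        n_reps, n = 10_000, 19
        x = rng.standard_normal((n_reps, n))
        y = rng.standard_normal((n_reps, n))
        _, p = sps.ttest_rel(x, y, axis=1)
        rate = float(np.mean(p < 0.05))
        assert 0.044 <= rate <= 0.056


def hand_rm_anova_2x2(cells: pd.DataFrame) -> dict[str, float]:
    """Classical sums-of-squares oracle for the 2x2 within-subject design.

    y[s, i, j]: subject s, probability level i, context j.  Each effect is
    tested against its own effect-by-subject interaction.
    """
    wide = cells.pivot_table(
        index="participant", columns=["probability", "context"],
        values="rt_ms",
    )
    n = wide.shape[0]
    y = wide.to_numpy().reshape(n, 2, 2)  # columns sorted: (high/low, A/B)
    grand = y.mean()
    m_s = y.mean(axis=(1, 2))  # per subject
    m_a = y.mean(axis=(0, 2))  # per probability level
    m_b = y.mean(axis=(0, 1))  # per context
    m_ab = y.mean(axis=0)
    m_as = y.mean(axis=2)
    m_bs = y.mean(axis=1)

    ss_a = n * 2 * ((m_a - grand) ** 2).sum()
    ss_as = 2 * (
        (m_as - m_a[None, :] - m_s[:, None] + grand) ** 2
    ).sum()
    ss_b = n * 2 * ((m_b - grand) ** 2).sum()
    ss_bs = 2 * (
        (m_bs - m_b[None, :] - m_s[:, None] + grand) ** 2
    ).sum()
    ss_ab = n * (
        (m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2
    ).sum()
    resid = (
        y
        - m_ab[None, :, :]
        - m_as[:, :, None]
        - m_bs[:, None, :]
        + m_a[None, :, None]
        + m_b[None, None, :]
        + m_s[:, None, None]
        - grand
    )
    ss_abs = (resid**2).sum()
    return {
        "probability": ss_a / (ss_as / (n - 1)),
        "context": ss_b / (ss_bs / (n - 1)),
        "interaction": ss_ab / (ss_abs / (n - 1)),
    }


class TestRtAnova:
    def _toy_cells(self) -> pd.DataFrame:
        rows = []
        rng = np.random.default_rng(5)
        base = {"p1": 1200.0, "p2": 1100.0, "p3": 1300.0}
        for pid in base:
            for prob in ("high", "low"):
                for ctx in ("A", "B"):
                    rt = (
                        base[pid]
                        + 80.0 * (prob == "high")
                        + 30.0 * (ctx == "B")
                        + rng.normal(0, 20)
                    )
                    rows.append(
                        {
                            "participant": pid,
                            "probability": prob,
                            "context": ctx,
                            "rt_ms": rt,
                        }
                    )
        return pd.DataFrame(rows)

    def test_matches_hand_sums_of_squares(self):
        cells = self._toy_cells()
        res = rt_anova_2x2(cells)
        oracle = hand_rm_anova_2x2(cells)
        for effect in ("probability", "context", "interaction"):
            assert res[effect].statistic == pytest.approx(
                oracle[effect], rel=1e-8
            ), effect
            assert res[effect].df == (1.0, 2.0)

    def test_no_condition_variance_gives_f_zero(self):
        rows = [
            {
                "participant": p,
                "probability": prob,
                "context": ctx,
                "rt_ms": 1000.0 + 10 * i,
            }
            for i, p in enumerate(["a", "b", "c"])
            for prob in ("high", "low")
            for ctx in ("A", "B")
        ]
        res = rt_anova_2x2(pd.DataFrame(rows))
        for effect in res.values():
            assert effect.statistic == pytest.approx(0.0, abs=1e-10)

    def test_constructed_probability_effect_detected(self):
        rng = np.random.default_rng(21)
        rows = []
        for p in range(8):
            for prob in ("high", "low"):
                for ctx in ("A", "B"):
                    rows.append(
                        {
                            "participant": f"s{p}",
                            "probability": prob,
                            "context": ctx,
                            "rt_ms": 1000.0
                            + 100.0 * (prob == "high")
                            + rng.normal(0, 5),
                        }
                    )
        res = rt_anova_2x2(pd.DataFrame(rows))
        assert res["probability"].pvalue < 1e-6
        assert res["context"].pvalue > 0.01

    def test_missing_cell_rejected(self):
        cells = self._toy_cells().iloc[:-1]
        with pytest.raises(ValueError):
            rt_anova_2x2(cells)

    def test_cell_means_from_sessions(self):
        sessions = [
            simulate_session(TaskConfig(), AgentParams(0.3, -3.0), s)
            for s in range(2)
        ]
        cells = rt_cell_means(sessions)
        assert set(cells["probability"]) <= {"high", "low"}
        assert cells.groupby("participant").size().le(4).all()


class TestTraitCorrelations:
    def test_perfect_linear_relation(self):
        effect = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        traits = pd.DataFrame({"reward_dependence": 2 * effect.to_numpy()},
                              index=effect.index)
        res = trait_correlations(effect, traits, n_scales=7)
        assert res["r"].iloc[0] == pytest.approx(1.0)
        assert res["threshold"].iloc[0] == pytest.approx(0.05 / 7)

    def test_bonferroni_constant(self):
        assert BONFERRONI_7 == pytest.approx(0.0071428571, abs=1e-9)
        assert round(BONFERRONI_7, 4) == 0.0071

    def test_null_coupling_rejection_rate(self):
        # per-scale rejection at 0.05/7 under a null cohort ~ 0.0071
        rng = np.random.default_rng(11)
        n, reps = 19, 1000
        hits, total = 0, 0
        for _ in range(reps):
            x = rng.standard_normal(n)
            y = rng.standard_normal((n, 7))
            r = (x - x.mean()) @ (y - y.mean(axis=0)) / (
                n * x.std() * y.std(axis=0)
            )
            t = r * np.sqrt((n - 2) / (1 - r**2))
            p = 2 * sps.t.sf(np.abs(t), n - 2)
            hits += int((p < BONFERRONI_7).sum())
            total += 7
        rate = hits / total
        assert abs(rate - BONFERRONI_7) < 3 * math.sqrt(
            BONFERRONI_7 * (1 - BONFERRONI_7) / total
        )

    def test_zero_variance_rejected(self):
        effect = pd.Series([1.0, 1.0, 1.0], index=list("abc"))
        traits = pd.DataFrame(
            {"novelty_seeking": [1.0, 2.0, 3.0]}, index=list("abc")
        )
        with pytest.raises(DegenerateDataError):
            trait_correlations(effect, traits)


class TestPower:
    def test_mean_effect_size(self):
        assert mean_effect_size(0.66, 0.78) == pytest.approx(0.72)
        assert mean_effect_size(0.5, 0.5) == 0.5

    def test_required_n_is_minimal(self):
        n = required_n(0.72, power=0.8, alpha=0.05)
        assert achieved_power(0.72, n) >= 0.8
        assert achieved_power(0.72, n - 1) < 0.8

    def test_required_n_monte_carlo_power(self):
        d, alpha = 0.72, 0.05
        n = required_n(d, power=0.8, alpha=alpha)
        rng = np.random.default_rng(55)
        reps = 4000
        x = rng.standard_normal((reps, n)) + d
        _, p = sps.ttest_1samp(x, 0.0, axis=1)
        sim_power = float(np.mean(p < alpha))
        mc_se = math.sqrt(0.8 * 0.2 / reps)
        assert sim_power >= 0.8 - 2 * mc_se
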