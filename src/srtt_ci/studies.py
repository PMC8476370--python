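"""Replication studies over simulated cohorts.

These are the operating-characteristic checks of the pipeline: the
type-I error of the factorial ANOVA on null cohorts, and the recovery
rate of the qualitative retention result pattern (per-cell difference
score signs plus the testing-day trend-test pattern) on paper-like
cohorts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import stats
from .metrics import participant_metrics
from .simulate import simulate_cohort


def _cohort_metrics(experiment, n_per_cell, preset, seed, accuracy_threshold=80.0):
    cohort = simulate_cohort(experiment, n_per_cell, preset, seed)
    rows = [participant_metrics(s, accuracy_threshold) for s in cohort.sims]
    df = pd.DataFrame(rows)
    return cohort, df[~df["excluded"]].reset_index(drop=True)


def type_i_error_rate(
    n_per_cell: int = 15,
    n_reps: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Rejection rate of the training main effect on null-preset cohorts.

    Each replication simulates a fresh retention cohort with all
    condition effects zero and runs the 2 x 2 factorial ANOVA on the
    retention difference score; the returned fraction should sit near
    ``alpha``.
    """
    ss = np.random.SeedSequence(seed)
    rejections = 0
    for child in ss.spawn(n_reps):
        _, df = _cohort_metrics("retention", n_per_cell, "null", child)
        results = stats.factorial_anova(
            df, ["training_condition", "testing_condition"], "retention"
        )
        p = next(r.p_value for r in results if r.term == "training_condition")
        rejections += p < alpha
    return rejections / n_reps


def _cell_mean_series(cohort, pids: set[str], day: int) -> np.ndarray:
    """Mean correct-trial RT per trial index across a cell's participants."""
    stack, masks = [], []
    for sim in cohort.sims:
        if sim.assignment.participant_id not in pids:
            continue
        d = sim.days[day]
        stack.append(d.trial_rt_sum)
        masks.append(d.trial_correct)
    rt = np.array(stack)
    ok = np.array(masks)
    with np.errstate(invalid="ignore"):
        series = np.where(ok, rt, np.nan)
        return np.nanmean(series, axis=0)


def retention_pattern_checks(
    n_per_cell: int = 20, seed: int | np.random.SeedSequence = 0, alpha: float = 0.05
) -> dict[str, bool]:
    """One paper-like retention replication, checked for the result shape.

    Sign pattern of the per-cell retention scores (BI positive,
    interleaved-trained cells non-positive) and the testing-day trend
    pattern (significant decreasing Mann-Kendall trend in II, BB and IB
    but not BI).
    """
    cohort, df = _cohort_metrics("retention", n_per_cell, "paper-like", seed)
    means = df.groupby("cell")["retention"].mean()
    checks = {
        "bi_positive": means.get("BI", np.nan) > 0,
        "ii_nonpositive": means.get("II", np.nan) <= 0,
        "ib_nonpositive": means.get("IB", np.nan) <= 0,
    }
    for cell in ("II", "BB", "IB", "BI"):
        pids = set(df.loc[df["cell"] == cell, "participant_id"])
        series = _cell_mean_series(cohort, pids, day=2)
        series = series[~np.isnan(series)]
        mk = stats.mann_kendall(series)
        significant_decrease = mk.p_value < alpha and mk.statistic < 0
        key = f"trend_{cell.lower()}"
        checks[key] = (not significant_decrease) if cell == "BI" else significant_decrease
    return checks


def pattern_recovery_rate(
    n_per_cell: int = 20,
    n_reps: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Fraction of paper-like replications recovering the full result shape."""
    ss = np.random.SeedSequence(seed)
    tallies: dict[str, int] = {}
    joint = 0
    for child in ss.spawn(n_reps):
        checks = retention_pattern_checks(n_per_cell, child, alpha)
        for k, v in checks.items():
            tallies[k] = tallies.get(k, 0) + bool(v)
        joint += all(checks.values())
    out = {k: v / n_reps for k, v in tallies.items()}
    out["joint"] = joint / n_reps
    return out
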