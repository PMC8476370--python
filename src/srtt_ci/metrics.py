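"""Analysis variables derived from trial logs.

Sequence RT is the sum of the eight key-press RTs of a trial; a trial
counts as correct only when all eight presses are correct, and only
correct trials enter the RT windows.  Windows follow the day's own
condition: blocked days use the first/last ten correct trials of each of
the three sequences (30 trials), interleaved days the first/last 30
correct trials regardless of label.  Difference scores (seconds,
negative = faster):

    retention = mean(first window, Day 2) - mean(last window, Day 1)
    learning  = mean(last window, Day 1) - mean(first window, Day 1)
    transfer  = mean(first window, Day 2) - mean(first window, Day 1)

Accuracy is per key press, in percent; participants below the accuracy
threshold (80% by default) on either day are flagged for exclusion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import GroupAssignment, TRIALS_PER_DAY
from .simulate import ParticipantSim

logger = logging.getLogger(__name__)

WINDOW_PER_SEQUENCE = 10  # blocked: last/first ten trials of each sequence
WINDOW_TOTAL = 30  # interleaved: last/first 30 trials
ACCURACY_THRESHOLD = 80.0  # percent, per day

SCORE_KINDS = ("retention", "learning", "transfer")


@dataclass(frozen=True)
class DifferenceScore:
    participant_id: str
    kind: str
    value: float
    window_n: int


def sequence_rts(log: pd.DataFrame) -> pd.DataFrame:
    """Collapse a per-press trial log to one record per sequence trial.

    Returns columns participant_id, day, trial_index, sequence_label,
    rt_sum, correct.  Incorrect trials are retained (consumers filter on
    ``correct``).  Malformed trials (press count != 8) raise with the
    offending trial named.
    """
    required = {"participant_id", "day", "trial_index", "sequence_label", "correct", "press_rt"}
    missing = required - set(log.columns)
    if missing:
        raise ValueError(f"trial log is missing columns {sorted(missing)}")
    grouped = log.groupby(["participant_id", "day", "trial_index"], sort=True)
    sizes = grouped.size()
    bad = sizes[sizes != 8]
    if len(bad):
        pid, day, trial = bad.index[0]
        raise ValueError(
            f"trial {trial} (participant {pid}, day {day}) has {bad.iloc[0]} presses, expected 8"
        )
    out = grouped.agg(
        sequence_label=("sequence_label", "first"),
        rt_sum=("press_rt", "sum"),
        correct=("correct", "all"),
    ).reset_index()
    return out


def sequence_rts_from_sim(sim: ParticipantSim) -> pd.DataFrame:
    """Fast path from the compact simulator arrays (same schema as above)."""
    frames = []
    pid = sim.assignment.participant_id
    for day, d in sorted(sim.days.items()):
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "day": day,
                    "trial_index": np.arange(len(d.labels)),
                    "sequence_label": d.labels,
                    "rt_sum": d.trial_rt_sum,
                    "correct": d.trial_correct,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def accuracy(log: pd.DataFrame, day: int) -> float:
    """Per-key-press accuracy on one day, in percent."""
    sub = log[log["day"] == day]
    if not len(sub):
        raise ValueError(f"no rows for day {day}")
    return float(sub["correct"].mean() * 100.0)


def sequence_accuracy(log: pd.DataFrame, day: int) -> float:
    """Per-sequence-trial accuracy (all eight presses correct), percent."""
    seq = sequence_rts(log)
    sub = seq[seq["day"] == day]
    return float(sub["correct"].mean() * 100.0)


def accuracy_from_sim(sim: ParticipantSim, day: int) -> float:
    return float(sim.days[day].correct.mean() * 100.0)


def exclusion_flag(acc_day1: float, acc_day2: float, threshold: float = ACCURACY_THRESHOLD):
    """(excluded, reason) under the either-day accuracy rule."""
    if acc_day1 < threshold or acc_day2 < threshold:
        return True, f"accuracy below {threshold:g}% (day1={acc_day1:.1f}%, day2={acc_day2:.1f}%)"
    return False, ""


def _window_mean_arrays(
    labels: np.ndarray,
    rt_sum: np.ndarray,
    correct: np.ndarray,
    condition: str,
    end: str,
) -> tuple[float, int]:
    """Window mean over correct trials; returns (mean, n_trials_used)."""
    if end not in ("first", "last"):
        raise ValueError("end must be 'first' or 'last'")
    take = (lambda x, k: x[:k]) if end == "first" else (lambda x, k: x[-k:])
    chunks = []
    if condition == "blocked":
        for lab in np.unique(labels):
            vals = rt_sum[(labels == lab) & correct]
            if len(vals) < WINDOW_PER_SEQUENCE:
                logger.warning(
                    "only %d correct trials for sequence %s (wanted %d); using all",
                    len(vals), lab, WINDOW_PER_SEQUENCE,
                )
            chunks.append(take(vals, WINDOW_PER_SEQUENCE))
    else:
        vals = rt_sum[correct]
        if len(vals) < WINDOW_TOTAL:
            logger.warning(
                "only %d correct trials (wanted %d); using all", len(vals), WINDOW_TOTAL
            )
        chunks.append(take(vals, WINDOW_TOTAL))
    pooled = np.concatenate(chunks) if chunks else np.array([])
    if not len(pooled):
        logger.warning("no correct trials in window; propagating missing value")
        return float("nan"), 0
    return float(pooled.mean()), int(len(pooled))


def window_mean(
    rts: pd.DataFrame,
    condition: str,
    day: int,
    end: str,
) -> float:
    """Mean sequence RT of the first/last window of a day (correct trials only)."""
    sub = rts[rts["day"] == day].sort_values("trial_index")
    mean, _ = _window_mean_arrays(
        sub["sequence_label"].to_numpy(),
        sub["rt_sum"].to_numpy(float),
        sub["correct"].to_numpy(bool),
        condition,
        end,
    )
    return mean


def difference_scores(
    rts: pd.DataFrame,
    assignment: GroupAssignment,
    experiment: str | None = None,
) -> list[DifferenceScore]:
    """Learning plus retention (Exp 1) or transfer (Exp 2) scores.

    Day-1 windows follow the training condition's rule and Day-2 windows
    the testing condition's, since each day's schedule defines what "per
    sequence" means.
    """
    experiment = experiment or assignment.experiment
    if experiment not in ("retention", "transfer"):
        raise ValueError(f"unknown experiment {experiment!r}")
    pid = assignment.participant_id
    sub = rts[rts["participant_id"] == pid] if "participant_id" in rts.columns else rts

    def window(day: int, condition: str, end: str) -> tuple[float, int]:
        s = sub[sub["day"] == day].sort_values("trial_index")
        return _window_mean_arrays(
            s["sequence_label"].to_numpy(),
            s["rt_sum"].to_numpy(float),
            s["correct"].to_numpy(bool),
            condition,
            end,
        )

    d1_first, n1f = window(1, assignment.training_condition, "first")
    d1_last, n1l = window(1, assignment.training_condition, "last")
    d2_first, n2f = window(2, assignment.testing_condition, "first")

    scores = [
        DifferenceScore(pid, "learning", d1_last - d1_first, min(n1f, n1l)),
    ]
    if experiment == "retention":
        scores.append(DifferenceScore(pid, "retention", d2_first - d1_last, min(n1l, n2f)))
    else:
        scores.append(DifferenceScore(pid, "transfer", d2_first - d1_first, min(n1f, n2f)))
    return scores


def participant_metrics(
    sim: ParticipantSim, accuracy_threshold: float = ACCURACY_THRESHOLD
) -> dict:
    """All per-participant analysis variables, computed on the fast path.

    Operates on the simulator's compact arrays directly (no intermediate
    trial-log frame), which keeps replication studies with hundreds of
    simulated cohorts cheap.
    """
    a = sim.assignment
    acc1 = accuracy_from_sim(sim, 1)
    acc2 = accuracy_from_sim(sim, 2)
    excluded, reason = exclusion_flag(acc1, acc2, accuracy_threshold)
    d1, d2 = sim.days[1], sim.days[2]

    def window(d, condition, end):
        return _window_mean_arrays(d.labels, d.trial_rt_sum, d.trial_correct, condition, end)

    d1_first, _ = window(d1, a.training_condition, "first")
    d1_last, _ = window(d1, a.training_condition, "last")
    d2_first, _ = window(d2, a.testing_condition, "first")
    scores = {"learning": d1_last - d1_first}
    if a.experiment == "retention":
        scores["retention"] = d2_first - d1_last
    else:
        scores["transfer"] = d2_first - d1_first
    return {
        "participant_id": a.participant_id,
        "experiment": a.experiment,
        "training_condition": a.training_condition,
        "testing_condition": a.testing_condition,
        "cell": a.cell,
        "accuracy_day1": acc1,
        "accuracy_day2": acc2,
        "excluded": excluded,
        "exclusion_reason": reason,
        **scores,
    }
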