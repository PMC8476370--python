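"""Orchestration: design -> simulate (or ingest) -> metrics -> recall -> stats.

``run_experiment`` executes the full experiment-shaped analysis for
either the retention or the transfer design and returns a
:class:`ReportBundle` of tables (learner counts, per-cell trend tests,
per-cell difference scores with SEM and one-sample t tests, the
exclusion log, the chance-calibration summary) plus the flat list of
test results.  Everything is seeded: the same config and seed reproduce
the bundle byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import metrics, recall as recall_mod, stats
from .design import Sequence, GroupAssignment
from .simulate import Cohort, RecallResponse, simulate_cohort

logger = logging.getLogger(__name__)

TRIAL_LOG_COLUMNS = [
    "participant_id",
    "day",
    "trial_index",
    "sequence_label",
    "press_index",
    "target_key",
    "response_key",
    "correct",
    "press_rt",
]


@dataclass
class RunConfig:
    """Reproducible description of one experiment-shaped run."""

    experiment: str = "retention"
    mode: str = "simulate"  # simulate | ingest
    seed: int = 0
    preset: str = "paper-like"
    n_per_cell: int = 20
    mc_comparisons: int = 2_000
    mc_reps: int = 200
    rule: str = "positional"
    cutoff_items: float = 3.0
    accuracy_threshold: float = 80.0
    run_length_cap: int = 2
    out_dir: str | None = None
    # ingest-mode inputs
    trial_log_path: str | None = None
    design_path: str | None = None
    recall_path: str | None = None
    rt_unit: str = "s"  # "s" or "ms"

    def __post_init__(self) -> None:
        if not 0.0 < self.accuracy_threshold <= 100.0:
            raise ValueError("accuracy_threshold must be in (0, 100]")
        if self.mode not in ("simulate", "ingest"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class ReportBundle:
    config: RunConfig
    cohort_table: pd.DataFrame
    learner_counts: pd.DataFrame
    trend_table: pd.DataFrame
    score_table: pd.DataFrame
    exclusion_log: pd.DataFrame
    stat_results: list[stats.StatResult]
    calibration: recall_mod.ChanceCalibration
    notes: list[str] = field(default_factory=list)

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.cohort_table.to_csv(out / "cohort.csv", index=False)
        self.learner_counts.to_csv(out / "learner_counts.csv")
        self.trend_table.to_csv(out / "trend_tests.csv", index=False)
        self.score_table.to_csv(out / "difference_scores.csv", index=False)
        self.exclusion_log.to_csv(out / "exclusions.csv", index=False)
        payload = {
            "config": dataclasses.asdict(self.config),
            "chance_calibration": self.calibration.to_dict(),
            "notes": self.notes,
            "results": [r.to_dict() for r in self.stat_results],
        }
        with open(out / "stat_results.json", "w") as fh:
            json.dump(payload, fh, indent=2)


# ---------------------------------------------------------------------------
# ingest
# ---------------------------------------------------------------------------

def ingest_triallog(
    path: str | Path,
    rt_unit: str = "s",
    column_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Read and validate a per-press trial-log CSV.

    ``column_map`` renames file columns to the documented schema; RTs in
    milliseconds are converted to seconds with ``rt_unit='ms'``.  Schema
    violations are reported with (0-based data) row numbers.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = set(TRIAL_LOG_COLUMNS) - set(df.columns) - {"correct"}
    if missing:
        raise ValueError(f"trial log {path} is missing columns {sorted(missing)}")
    if "correct" not in df.columns:
        df["correct"] = df["target_key"] == df["response_key"]
    if rt_unit == "ms":
        df["press_rt"] = df["press_rt"] / 1000.0
    elif rt_unit != "s":
        raise ValueError(f"unknown rt unit {rt_unit!r}")
    # each trial must contribute exactly 8 presses
    sizes = df.groupby(["participant_id", "day", "trial_index"]).size()
    bad = sizes[sizes != 8]
    if len(bad):
        pid, day, trial = bad.index[0]
        rows = df.index[
            (df["participant_id"] == pid) & (df["day"] == day) & (df["trial_index"] == trial)
        ].tolist()
        raise ValueError(
            f"trial {trial} of participant {pid} day {day} has {bad.iloc[0]} presses "
            f"(rows {rows[:3]}...)"
        )
    # trial indices must be 0..n-1 within each participant-day
    for (pid, day), sub in df.groupby(["participant_id", "day"]):
        idx = np.sort(sub["trial_index"].unique())
        if not np.array_equal(idx, np.arange(len(idx))):
            first_bad = int(np.flatnonzero(idx != np.arange(len(idx)))[0])
            raise ValueError(
                f"participant {pid} day {day}: trial indices not contiguous near {idx[first_bad]}"
            )
    return df[TRIAL_LOG_COLUMNS]


def _assignments_from_design(design_df: pd.DataFrame) -> dict[str, GroupAssignment]:
    out = {}
    for pid, sub in design_df.groupby("participant_id"):
        row = sub.iloc[0]
        out[pid] = GroupAssignment(
            participant_id=pid,
            training_condition=row["training_condition"],
            testing_condition=row["testing_condition"],
            experiment=row["experiment"],
        )
    return out


def _truths_from_design(design_df: pd.DataFrame, pid: str) -> dict[str, Sequence]:
    sub = design_df[design_df["participant_id"] == pid]
    truths = {}
    for lab, rows in sub.groupby("sequence_label"):
        first_trial = rows[rows["trial_index"] == rows["trial_index"].min()]
        first_trial = first_trial[first_trial["day"] == first_trial["day"].min()]
        items = tuple(first_trial.sort_values("item_position")["target_key"])
        truths[lab] = Sequence(items=items, label=lab)
    return truths


# ---------------------------------------------------------------------------
# analysis
# ---------------------------------------------------------------------------

def _cell_mean_series(seq_df: pd.DataFrame, day: int) -> pd.Series:
    """Per-trial mean correct-trial RT across the participants in seq_df."""
    sub = seq_df[(seq_df["day"] == day) & seq_df["correct"]]
    return sub.groupby("trial_index")["rt_sum"].mean()


def _trend_table(seq_df: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    """Mann-Kendall trend tests on cell-mean RT series, both days.

    Day 1 is summarized per training condition (as during training) and
    Day 2 per training/testing cell (the testing-day table).
    """
    rows = []
    for cond in sorted(cohort["training_condition"].unique()):
        pids = cohort.loc[cohort["training_condition"] == cond, "participant_id"]
        series = _cell_mean_series(seq_df[seq_df["participant_id"].isin(pids)], day=1)
        mk = stats.mann_kendall(series.to_numpy())
        rows.append(("1", cond, mk.statistic, mk.p_value, len(series)))
    for cell in sorted(cohort["cell"].unique()):
        pids = cohort.loc[cohort["cell"] == cell, "participant_id"]
        series = _cell_mean_series(seq_df[seq_df["participant_id"].isin(pids)], day=2)
        mk = stats.mann_kendall(series.to_numpy())
        rows.append(("2", cell, mk.statistic, mk.p_value, len(series)))
    return pd.DataFrame(rows, columns=["day", "group", "tau", "p_value", "n_trials"])


def _score_table(cohort: pd.DataFrame, score_col: str) -> pd.DataFrame:
    """Per-cell difference-score summary with SEM and one-sample t vs 0."""
    rows = []
    for cell in sorted(cohort["cell"].unique()):
        vals = cohort.loc[cohort["cell"] == cell, score_col].dropna().to_numpy(float)
        t = p = float("nan")
        if len(vals) >= 2 and np.std(vals, ddof=1) > 0:
            res = stats.one_sample_t(vals, 0.0)
            t, p = res.statistic, res.p_value
        rows.append(
            (
                cell,
                len(vals),
                float(np.mean(vals)) if len(vals) else float("nan"),
                float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan"),
                float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else float("nan"),
                t,
                p,
            )
        )
    return pd.DataFrame(
        rows, columns=["cell", "n", "mean", "sd", "sem", "t_vs_zero", "p_vs_zero"]
    )


def _accuracy_battery(cohort: pd.DataFrame) -> list[stats.StatResult]:
    """The paper-shaped accuracy comparisons (Mann-Whitney)."""
    out = []

    def grab(col, mask):
        return cohort.loc[mask, col].to_numpy(float)

    comparisons = [
        ("accuracy_day1 interleaved-vs-blocked training",
         grab("accuracy_day1", cohort["training_condition"] == "interleaved"),
         grab("accuracy_day1", cohort["training_condition"] == "blocked")),
        ("accuracy_day2 interleaved-vs-blocked testing",
         grab("accuracy_day2", cohort["testing_condition"] == "interleaved"),
         grab("accuracy_day2", cohort["testing_condition"] == "blocked")),
        ("accuracy_day2 II-vs-BI",
         grab("accuracy_day2", cohort["cell"] == "II"),
         grab("accuracy_day2", cohort["cell"] == "BI")),
        ("accuracy_day2 BB-vs-IB",
         grab("accuracy_day2", cohort["cell"] == "BB"),
         grab("accuracy_day2", cohort["cell"] == "IB")),
    ]
    for term, a, b in comparisons:
        if len(a) and len(b):
            res = stats.mann_whitney_u(a, b)
            res.term = term
            out.append(res)
    return out


def _stat_battery(
    cohort: pd.DataFrame, experiment: str, notes: list[str]
) -> list[stats.StatResult]:
    score_col = "retention" if experiment == "retention" else "transfer"
    results: list[stats.StatResult] = []

    # recall comparison between training conditions
    a = cohort.loc[cohort["training_condition"] == "interleaved", "recall_items"]
    b = cohort.loc[cohort["training_condition"] == "blocked", "recall_items"]
    try:
        res = stats.independent_t(a, b)
        res.term = "recall_items interleaved-vs-blocked training"
        results.append(res)
    except ValueError as err:
        notes.append(f"recall t test skipped: {err}")

    # factorial ANOVA on the difference score
    factors = ["training_condition", "testing_condition"]
    if experiment == "retention" and cohort["learner_class"].nunique() == 2:
        try:
            results.extend(
                stats.factorial_anova(cohort, factors + ["learner_class"], score_col)
            )
        except ValueError as err:
            notes.append(f"2x2x2 ANOVA reduced to 2x2: {err}")
            results.extend(stats.factorial_anova(cohort, factors, score_col))
    else:
        results.extend(stats.factorial_anova(cohort, factors, score_col))
    results.extend(
        stats.simple_effects(cohort, "testing_condition", "training_condition", score_col)
    )
    results.extend(stats.ancova(cohort, factors, "recall_items", score_col))
    if experiment == "transfer":
        results.extend(stats.tukey_pairwise(cohort, "cell", score_col))

    # learning during training: one-sample per condition plus the contrast
    for cond in ("blocked", "interleaved"):
        vals = cohort.loc[cohort["training_condition"] == cond, "learning"].dropna()
        try:
            res = stats.one_sample_t(vals)
            res.term = f"learning score vs 0, {cond} training"
            results.append(res)
        except ValueError as err:
            notes.append(f"learning t test ({cond}) skipped: {err}")
    try:
        res = stats.independent_t(
            cohort.loc[cohort["training_condition"] == "blocked", "learning"].dropna(),
            cohort.loc[cohort["training_condition"] == "interleaved", "learning"].dropna(),
        )
        res.term = "learning score blocked-vs-interleaved"
        results.append(res)
    except ValueError as err:
        notes.append(f"learning contrast skipped: {err}")

    results.extend(_accuracy_battery(cohort))
    return results


def _cohort_tables(config: RunConfig):
    """Produce (cohort_df, seq_df, participants' truths) for either mode."""
    if config.mode == "simulate":
        ss = np.random.SeedSequence(config.seed)
        cohort_seed, _ = ss.spawn(2)
        cohort = simulate_cohort(
            config.experiment,
            config.n_per_cell,
            config.preset,
            cohort_seed,
            config.run_length_cap,
        )
        rows, seq_frames = [], []
        for sim in cohort.sims:
            row = metrics.participant_metrics(sim, config.accuracy_threshold)
            if sim.assignment.experiment == "transfer":
                labels = sim.design.day1_labels + sim.design.day2_labels
            else:
                labels = sim.design.day1_labels
            truths = [sim.design.sequences[lab] for lab in labels]
            score = recall_mod.score_recall(
                sim.recall, truths, config.rule, config.cutoff_items
            )
            row["recall_items"] = score.items_per_sequence
            row["learner_class"] = score.learner_class
            rows.append(row)
            seq_frames.append(metrics.sequence_rts_from_sim(sim))
        return pd.DataFrame(rows), pd.concat(seq_frames, ignore_index=True)

    # ingest mode
    for name in ("trial_log_path", "design_path", "recall_path"):
        if getattr(config, name) is None:
            raise ValueError(f"ingest mode requires {name}")
    log = ingest_triallog(config.trial_log_path, rt_unit=config.rt_unit)
    design_df = pd.read_csv(config.design_path)
    with open(config.recall_path) as fh:
        recall_data = {r["participant_id"]: r for r in json.load(fh)}
    assignments = _assignments_from_design(design_df)
    seq_df = metrics.sequence_rts(log)
    rows = []
    for pid, assignment in assignments.items():
        sub = log[log["participant_id"] == pid]
        acc1 = metrics.accuracy(sub, 1)
        acc2 = metrics.accuracy(sub, 2)
        excluded, reason = metrics.exclusion_flag(acc1, acc2, config.accuracy_threshold)
        prts = seq_df[seq_df["participant_id"] == pid]
        scores = {
            s.kind: s.value for s in metrics.difference_scores(prts, assignment)
        }
        truths = list(_truths_from_design(design_df, pid).values())
        typed = recall_data.get(pid, {}).get("typed_sequences", [])
        score = recall_mod.score_recall(typed, truths, config.rule, config.cutoff_items)
        rows.append(
            {
                "participant_id": pid,
                "experiment": assignment.experiment,
                "training_condition": assignment.training_condition,
                "testing_condition": assignment.testing_condition,
                "cell": assignment.cell,
                "accuracy_day1": acc1,
                "accuracy_day2": acc2,
                "excluded": excluded,
                "exclusion_reason": reason,
                **scores,
                "recall_items": score.items_per_sequence,
                "learner_class": score.learner_class,
            }
        )
    return pd.DataFrame(rows), seq_df


def run_experiment(config: RunConfig) -> ReportBundle:
    """Run the full experiment-shaped pipeline described by ``config``."""
    notes: list[str] = []
    cohort_df, seq_df = _cohort_tables(config)
    score_col = "retention" if config.experiment == "retention" else "transfer"

    exclusion_log = cohort_df[cohort_df["excluded"]][
        ["participant_id", "cell", "accuracy_day1", "accuracy_day2", "exclusion_reason"]
    ].reset_index(drop=True)
    included = cohort_df[~cohort_df["excluded"]].reset_index(drop=True)
    logger.info(
        "stage=exclusion n_in=%d n_excluded=%d", len(cohort_df), len(exclusion_log)
    )

    calib_seed = np.random.SeedSequence(config.seed).spawn(2)[1]
    calibration = recall_mod.calibrate_chance(
        config.mc_comparisons, config.mc_reps, config.rule, np.random.default_rng(calib_seed)
    )

    if included.empty:
        notes.append("all participants excluded; analysis tables are empty")
        empty = pd.DataFrame()
        return ReportBundle(
            config=config,
            cohort_table=cohort_df,
            learner_counts=empty,
            trend_table=empty,
            score_table=empty,
            exclusion_log=exclusion_log,
            stat_results=[],
            calibration=calibration,
            notes=notes,
        )

    seq_included = seq_df[seq_df["participant_id"].isin(included["participant_id"])]
    learner_counts = (
        included.pivot_table(
            index="cell", columns="learner_class", values="participant_id", aggfunc="count"
        )
        .fillna(0)
        .astype(int)
    )
    trend_table = _trend_table(seq_included, included)
    score_table = _score_table(included, score_col)
    stat_results = _stat_battery(included, config.experiment, notes)

    bundle = ReportBundle(
        config=config,
        cohort_table=cohort_df,
        learner_counts=learner_counts,
        trend_table=trend_table,
        score_table=score_table,
        exclusion_log=exclusion_log,
        stat_results=stat_results,
        calibration=calibration,
        notes=notes,
    )
    if config.out_dir:
        bundle.save(config.out_dir)
    return bundle
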