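"""Synthetic-participant generator for the two-day SRTT design.

No public trial-level data exist for this paradigm, so every downstream
stage is exercised against a generative stand-in.  Per-press reaction
time is modeled as a baseline plus three exponentially decaying learning
terms -- nonspecific (practice across the whole task), sequence-specific
(exposures to the current sequence) and a per-session warm-up -- plus an
additive switch cost on trials whose sequence differs from the previous
trial's, an overnight consolidation offset applied on Day 2, and
Gaussian press noise truncated at a reaction-time floor:

    rt = max(floor, base
                    + general_gain * exp(-t / general_tau)
                    + seq_gain * exp(-e / seq_tau)
                    + session_gain * exp(-d / session_tau)
                    + switch_cost * [switch]
                    + consolidation_offset * [day 2]
                    + Normal(0, press_noise_sd))

with t the cumulative trial index, e the number of prior exposures to
the trial's sequence and d the within-session trial index.  A scale
``day2_learning`` in [0, 1] throttles how much the decay indices advance
on Day 2 (0 = no further improvement at test, as blocked-trained
participants show under interleaved testing).  Errors are independent
per press; the response is the target with probability 1 - error_prob,
else a uniformly chosen wrong key.

Cohort presets ("null", "paper-like", "transfer-like") pin the
parameters to the study conditions; see docs/methods.md for the
derivation of each preset from the qualitative result patterns it is
defined to reproduce.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .design import (
    KEYS,
    SEQUENCE_LENGTH,
    TRIALS_PER_DAY,
    GroupAssignment,
    ParticipantDesign,
    Schedule,
    Sequence,
    build_experiment_design,
)

KEY_INDEX = {k: i for i, k in enumerate(KEYS)}


@dataclass(frozen=True)
class ParticipantParams:
    """Generative parameters for one synthetic participant (seconds / trials)."""

    base_press_rt: float = 0.30
    general_gain: float = 0.10
    general_tau: float = 60.0
    seq_gain: float = 0.08
    seq_tau: float = 30.0
    switch_cost: float = 0.02
    press_noise_sd: float = 0.09
    press_error_prob: float = 0.05
    consolidation_offset: float = 0.0
    explicit_k: int = 0
    rt_floor: float = 0.15
    # session-level terms beyond the minimal model
    session_gain: float = 0.0
    session_tau: float = 80.0
    switch_cost_day2: float | None = None  # None -> same as switch_cost
    press_error_prob_day2: float | None = None  # None -> same as Day 1
    day2_learning: float = 1.0  # 0 = frozen at end-of-training level on Day 2
    post_error_cost: float = 0.0  # additive cost on the press after an error

    def __post_init__(self) -> None:
        for name in (
            "base_press_rt",
            "general_gain",
            "general_tau",
            "seq_gain",
            "seq_tau",
            "press_noise_sd",
            "rt_floor",
            "session_gain",
            "session_tau",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("press_error_prob", "day2_learning"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.explicit_k not in range(SEQUENCE_LENGTH + 1):
            raise ValueError("explicit_k must be an integer in 0..8")

    def error_prob(self, day: int) -> float:
        if day == 2 and self.press_error_prob_day2 is not None:
            return self.press_error_prob_day2
        return self.press_error_prob

    def switch_cost_for(self, day: int) -> float:
        if day == 2 and self.switch_cost_day2 is not None:
            return self.switch_cost_day2
        return self.switch_cost


@dataclass(frozen=True)
class RecallResponse:
    participant_id: str
    noticed_pattern: bool
    reported_count: int
    typed_sequences: list[str]

    def to_dict(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "noticed_pattern": self.noticed_pattern,
            "reported_count": self.reported_count,
            "typed_sequences": list(self.typed_sequences),
        }


@dataclass
class DaySim:
    """Compact per-day arrays: 240 trials x 8 presses."""

    day: int
    labels: np.ndarray  # (240,) sequence labels
    targets: np.ndarray  # (240, 8) int8 key codes
    responses: np.ndarray  # (240, 8) int8 key codes
    correct: np.ndarray  # (240, 8) bool
    press_rt: np.ndarray  # (240, 8) float seconds
    is_switch: np.ndarray  # (240,) bool

    @property
    def trial_rt_sum(self) -> np.ndarray:
        return self.press_rt.sum(axis=1)

    @property
    def trial_correct(self) -> np.ndarray:
        return self.correct.all(axis=1)


@dataclass
class ParticipantSim:
    """One synthetic participant: design, parameters, and both days' logs."""

    design: ParticipantDesign
    params: ParticipantParams
    days: dict[int, DaySim]
    recall: RecallResponse

    @property
    def assignment(self) -> GroupAssignment:
        return self.design.assignment

    def to_frame(self) -> pd.DataFrame:
        """Materialize the trial log (one row per key press)."""
        frames = []
        pid = self.assignment.participant_id
        keys = np.array(KEYS)
        for day, d in sorted(self.days.items()):
            n_tr, n_pr = d.press_rt.shape
            frames.append(
                pd.DataFrame(
                    {
                        "participant_id": pid,
                        "day": day,
                        "trial_index": np.repeat(np.arange(n_tr), n_pr),
                        "sequence_label": np.repeat(d.labels, n_pr),
                        "press_index": np.tile(np.arange(n_pr), n_tr),
                        "target_key": keys[d.targets.ravel()],
                        "response_key": keys[d.responses.ravel()],
                        "correct": d.correct.ravel(),
                        "press_rt": d.press_rt.ravel(),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def simulate_press_rt(
    params: ParticipantParams,
    trial_index: int,
    exposures_of_sequence: int,
    is_switch: bool,
    rng: np.random.Generator,
    day: int = 1,
    session_trial_index: float | None = None,
) -> float:
    """Draw one press RT from the generative model (scalar reference path).

    ``trial_index`` is the cumulative trial count, ``exposures_of_sequence``
    the number of prior trials of the same sequence, and
    ``session_trial_index`` the within-session index for the warm-up term
    (defaults to ``trial_index``).  Deterministic given the generator state.
    """
    if trial_index < 0 or exposures_of_sequence < 0:
        raise ValueError("indices must be >= 0")
    d = trial_index if session_trial_index is None else session_trial_index
    rt = (
        params.base_press_rt
        + params.general_gain * np.exp(-trial_index / params.general_tau)
        + params.seq_gain * np.exp(-exposures_of_sequence / params.seq_tau)
        + params.session_gain * np.exp(-d / params.session_tau)
        + params.switch_cost_for(day) * bool(is_switch)
        + (params.consolidation_offset if day == 2 else 0.0)
        + rng.normal(0.0, params.press_noise_sd)
    )
    return max(params.rt_floor, float(rt))


def expected_press_rt(
    params: ParticipantParams,
    trial_index: float,
    exposures_of_sequence: float,
    is_switch: bool = False,
    day: int = 1,
    session_trial_index: float | None = None,
) -> float:
    """Noise-free expectation of the press RT (ignores floor truncation)."""
    d = trial_index if session_trial_index is None else session_trial_index
    return (
        params.base_press_rt
        + params.general_gain * np.exp(-trial_index / params.general_tau)
        + params.seq_gain * np.exp(-exposures_of_sequence / params.seq_tau)
        + params.session_gain * np.exp(-d / params.session_tau)
        + params.switch_cost_for(day) * bool(is_switch)
        + (params.consolidation_offset if day == 2 else 0.0)
    )


def _day_indices(schedule: Schedule, exposure_start: dict[str, int]):
    """Per-trial exposure counts, switch flags and label codes for one day."""
    labels = np.array(schedule.trials)
    n = len(labels)
    exposures = np.zeros(n)
    counts = dict(exposure_start)
    for i, lab in enumerate(labels):
        c = counts.get(lab, 0)
        exposures[i] = c
        counts[lab] = c + 1
    is_switch = np.zeros(n, dtype=bool)
    is_switch[1:] = labels[1:] != labels[:-1]
    return labels, exposures, is_switch, counts


def _simulate_day(
    design: ParticipantDesign,
    params: ParticipantParams,
    schedule: Schedule,
    exposure_start: dict[str, int],
    rng: np.random.Generator,
) -> tuple[DaySim, dict[str, int]]:
    day = schedule.day
    labels, exposures, is_switch, counts = _day_indices(schedule, exposure_start)
    n = len(labels)
    d_idx = np.arange(n, dtype=float)
    if day == 1:
        t_eff = d_idx
        sess_eff = d_idx
        e_eff = exposures
    else:
        s = params.day2_learning
        t_eff = TRIALS_PER_DAY + s * d_idx
        sess_eff = s * d_idx
        e_start = np.array([exposure_start.get(lab, 0) for lab in labels], dtype=float)
        e_eff = e_start + s * (exposures - e_start)
    trial_mean = (
        params.base_press_rt
        + params.general_gain * np.exp(-t_eff / params.general_tau)
        + params.seq_gain * np.exp(-e_eff / params.seq_tau)
        + params.session_gain * np.exp(-sess_eff / params.session_tau)
        + params.switch_cost_for(day) * is_switch
        + (params.consolidation_offset if day == 2 else 0.0)
    )
    noise = rng.normal(0.0, params.press_noise_sd, size=(n, SEQUENCE_LENGTH))
    press_rt = np.maximum(params.rt_floor, trial_mean[:, None] + noise)

    targets = np.empty((n, SEQUENCE_LENGTH), dtype=np.int8)
    for lab in schedule.labels:
        row = np.array([KEY_INDEX[k] for k in design.sequences[lab].items], dtype=np.int8)
        targets[labels == lab] = row
    p_err = params.error_prob(day)
    err = rng.random((n, SEQUENCE_LENGTH)) < p_err
    # a wrong press is uniform over the three non-target keys
    shift = rng.integers(1, len(KEYS), size=(n, SEQUENCE_LENGTH)).astype(np.int8)
    responses = np.where(err, (targets + shift) % len(KEYS), targets).astype(np.int8)
    if params.post_error_cost > 0.0:
        lagged = np.zeros_like(err)
        lagged[:, 1:] = err[:, :-1]
        press_rt = press_rt + params.post_error_cost * lagged
    sim = DaySim(
        day=day,
        labels=labels,
        targets=targets,
        responses=responses,
        correct=~err,
        press_rt=press_rt,
        is_switch=is_switch,
    )
    return sim, counts


def _random_completion(prefix: tuple[str, ...], rng: np.random.Generator) -> str:
    """Complete a partial recall to a valid-format 8-key string."""
    remaining = list(KEYS * 2)
    for k in prefix:
        remaining.remove(k)
    order = rng.permutation(len(remaining))
    return "".join(prefix) + "".join(remaining[i] for i in order)


def _generate_recall(
    design: ParticipantDesign, params: ParticipantParams, rng: np.random.Generator
) -> RecallResponse:
    """Recall of the first ``explicit_k`` items of each relevant sequence.

    Retention participants recall against the three (repeated) sequences;
    transfer participants were asked about both days, so they draw from
    the Day-1 and Day-2 pools (six sequences).
    """
    if design.assignment.experiment == "transfer":
        truth_labels = design.day1_labels + design.day2_labels
    else:
        truth_labels = design.day1_labels
    k = params.explicit_k
    typed = [
        _random_completion(design.sequences[lab].items[:k], rng) for lab in truth_labels
    ]
    noticed = k >= 1 or rng.random() < 0.5
    n_true = len(truth_labels)
    reported = n_true if k >= 2 else int(rng.integers(1, n_true + 2))
    return RecallResponse(
        participant_id=design.assignment.participant_id,
        noticed_pattern=bool(noticed),
        reported_count=reported,
        typed_sequences=typed,
    )


def simulate_participant(
    design: ParticipantDesign,
    params: ParticipantParams,
    rng_seed: int | np.random.Generator,
) -> ParticipantSim:
    """Simulate both days of one participant plus their free recall."""
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    day1, counts = _simulate_day(design, params, design.schedule_day1, {}, rng)
    if design.assignment.experiment == "transfer":
        counts = {lab: 0 for lab in design.day2_labels}  # novel sequences start fresh
    day2, _ = _simulate_day(design, params, design.schedule_day2, counts, rng)
    recall = _generate_recall(design, params, rng)
    return ParticipantSim(design=design, params=params, days={1: day1, 2: day2}, recall=recall)


# ---------------------------------------------------------------------------
# cohort presets
# ---------------------------------------------------------------------------

def _null_preset(assignment: GroupAssignment, rng: np.random.Generator) -> ParticipantParams:
    """All condition effects zero: flat mean RT, equal error rates."""
    return ParticipantParams(
        base_press_rt=0.30,
        general_gain=0.0,
        seq_gain=0.0,
        switch_cost=0.0,
        session_gain=0.0,
        press_noise_sd=0.09,
        press_error_prob=0.05,
        consolidation_offset=0.0,
        explicit_k=0,
    )


def _paper_like_preset(assignment: GroupAssignment, rng: np.random.Generator) -> ParticipantParams:
    """Retention-experiment effect configuration.

    Blocked practice expresses sequence learning quickly (short seq_tau)
    but consolidates poorly overnight and pays a heavy switch cost when
    tested interleaved, with no further improvement in that cell;
    interleaved practice learns slowly during training, consolidates
    overnight, and is robust to either testing condition.
    """
    blocked_trained = assignment.training_condition == "blocked"
    interleaved_tested = assignment.testing_condition == "interleaved"
    return ParticipantParams(
        base_press_rt=0.30,
        general_gain=0.04,
        general_tau=40.0,
        seq_gain=0.08,
        seq_tau=25.0 if blocked_trained else 400.0,
        session_gain=0.03,
        session_tau=80.0,
        switch_cost=0.02,
        switch_cost_day2=0.05 if blocked_trained else 0.01,
        press_noise_sd=0.09,
        press_error_prob=0.058 if blocked_trained else 0.077,
        press_error_prob_day2=0.060 if interleaved_tested else 0.044,
        consolidation_offset=float(
            (0.03 if blocked_trained else -0.03) + rng.normal(0.0, 0.015)
        ),
        day2_learning=0.0 if (blocked_trained and interleaved_tested) else 1.0,
        explicit_k=int(rng.binomial(SEQUENCE_LENGTH, 0.36 if blocked_trained else 0.20)),
    )


def _transfer_like_preset(assignment: GroupAssignment, rng: np.random.Generator) -> ParticipantParams:
    """Transfer-experiment effect configuration.

    Overnight consolidation of general (sequence-unspecific) skill speeds
    everyone up on novel sequences, more so after interleaved training;
    blocked-trained participants facing interleaved novel sequences pay a
    large switch cost and show no Day-2 improvement, netting ~zero
    transfer in the BI cell.  Explicit knowledge stays near chance.
    """
    blocked_trained = assignment.training_condition == "blocked"
    interleaved_tested = assignment.testing_condition == "interleaved"
    return ParticipantParams(
        base_press_rt=0.30,
        general_gain=0.04,
        general_tau=40.0,
        seq_gain=0.08,
        seq_tau=25.0 if blocked_trained else 400.0,
        session_gain=0.03,
        session_tau=80.0,
        switch_cost=0.02,
        switch_cost_day2=0.045 if blocked_trained else 0.01,
        press_noise_sd=0.09,
        press_error_prob=0.053 if blocked_trained else 0.089,
        press_error_prob_day2=0.058 if interleaved_tested else 0.043,
        consolidation_offset=float(
            (-0.055 if blocked_trained else -0.056) + rng.normal(0.0, 0.015)
        ),
        day2_learning=0.0 if (blocked_trained and interleaved_tested) else 1.0,
        explicit_k=int(rng.binomial(SEQUENCE_LENGTH, 0.05)),
    )


PRESETS: dict[str, Callable[[GroupAssignment, np.random.Generator], ParticipantParams]] = {
    "null": _null_preset,
    "paper-like": _paper_like_preset,
    "transfer-like": _transfer_like_preset,
}
# underscore aliases for config-file convenience
PRESETS["paper_like"] = _paper_like_preset
PRESETS["transfer_like"] = _transfer_like_preset


@dataclass
class Cohort:
    experiment: str
    preset: str
    sims: list[ParticipantSim]

    @property
    def designs(self) -> list[ParticipantDesign]:
        return [s.design for s in self.sims]

    @property
    def recalls(self) -> list[RecallResponse]:
        return [s.recall for s in self.sims]

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([s.to_frame() for s in self.sims], ignore_index=True)


def simulate_cohort(
    experiment: str,
    n_per_cell: int,
    preset: str = "paper-like",
    rng_seed: int | np.random.SeedSequence = 0,
    run_length_cap: int = 2,
) -> Cohort:
    """Simulate a counterbalanced cohort of 4 * n_per_cell participants."""
    if n_per_cell < 1:
        raise ValueError("n_per_cell must be >= 1")
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; available: {sorted(PRESETS)}")
    ss = rng_seed if isinstance(rng_seed, np.random.SeedSequence) else np.random.SeedSequence(rng_seed)
    design_seed, *participant_seeds = ss.spawn(1 + 4 * n_per_cell)
    designs = build_experiment_design(
        experiment, 4 * n_per_cell, np.random.default_rng(design_seed), run_length_cap
    )
    make_params = PRESETS[preset]
    sims = []
    for design, child in zip(designs, participant_seeds):
        rng = np.random.default_rng(child)
        params = make_params(design.assignment, rng)
        sims.append(simulate_participant(design, params, rng))
    return Cohort(experiment=experiment, preset=preset, sims=sims)
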