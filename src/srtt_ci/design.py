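"""Experimental-design generation for the two-day SRTT study.

A participant practices three eight-item key sequences over the keys
U, I, O, P (each key appearing exactly twice per sequence).  On each day
the three sequences are presented 80 times each, for 240 trials, either
*blocked* (AAA...BBB...CCC) or *interleaved* (ACBABC...).  Day 2 reuses
the Day-1 sequences in the retention experiment and introduces three
novel sequences in the transfer experiment.  Participants are assigned,
counterbalanced, to one of the four training/testing cells BB, II, BI,
IB.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence as TypingSequence

import numpy as np
import pandas as pd
from sympy.utilities.iterables import multiset_permutations

KEYS: tuple[str, ...] = ("U", "I", "O", "P")
SEQUENCE_LENGTH = 8
KEY_COPIES = 2
PRESENTATIONS_PER_SEQUENCE = 80
N_SEQUENCES_PER_DAY = 3
TRIALS_PER_DAY = PRESENTATIONS_PER_SEQUENCE * N_SEQUENCES_PER_DAY

DAY1_LABELS: tuple[str, ...] = ("A", "B", "C")
DAY2_NOVEL_LABELS: tuple[str, ...] = ("D", "E", "F")

#: the four training/testing cells, in the conventional order BB, II, BI, IB
CELLS: tuple[tuple[str, str], ...] = (
    ("blocked", "blocked"),
    ("interleaved", "interleaved"),
    ("blocked", "interleaved"),
    ("interleaved", "blocked"),
)

CONDITIONS = ("blocked", "interleaved")
EXPERIMENTS = ("retention", "transfer")


def _as_rng(rng: int | np.random.Generator | np.random.SeedSequence) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class Sequence:
    """An ordered 8-item key sequence over {U, I, O, P}, each key twice."""

    items: tuple[str, ...]
    label: str = "A"

    def __post_init__(self) -> None:
        if len(self.items) != SEQUENCE_LENGTH:
            raise ValueError(f"sequence must have {SEQUENCE_LENGTH} items, got {len(self.items)}")
        for key in KEYS:
            n = self.items.count(key)
            if n != KEY_COPIES:
                raise ValueError(f"key {key!r} occurs {n} times, expected {KEY_COPIES}")

    def __str__(self) -> str:
        return "".join(self.items)


@dataclass(frozen=True)
class Schedule:
    """One participant-day ordering of 240 sequence trials."""

    condition: str
    day: int
    trials: tuple[str, ...]
    experiment: str = "retention"
    run_length_cap: int | None = None

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        labels = sorted(set(self.trials))
        if len(self.trials) != PRESENTATIONS_PER_SEQUENCE * len(labels):
            raise ValueError("schedule length inconsistent with label count")
        for lab in labels:
            n = self.trials.count(lab)
            if n != PRESENTATIONS_PER_SEQUENCE:
                raise ValueError(f"label {lab!r} occurs {n} times, expected {PRESENTATIONS_PER_SEQUENCE}")
        runs = run_lengths(self.trials)
        if self.condition == "blocked" and len(runs) != len(labels):
            raise ValueError("blocked schedule must be contiguous runs, one per label")
        if self.condition == "interleaved" and self.run_length_cap is not None:
            worst = max(r for _, r in runs)
            if worst > self.run_length_cap:
                raise ValueError(f"run of length {worst} exceeds cap {self.run_length_cap}")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.trials)))


@dataclass(frozen=True)
class GroupAssignment:
    participant_id: str
    training_condition: str
    testing_condition: str
    experiment: str

    @property
    def cell(self) -> str:
        """Short cell code: BB, II, BI or IB (training then testing)."""
        return self.training_condition[0].upper() + self.testing_condition[0].upper()


@dataclass(frozen=True)
class ParticipantDesign:
    """Everything fixed about one participant before any key is pressed."""

    assignment: GroupAssignment
    sequences: dict[str, Sequence]  # label -> Sequence, covering both days
    schedule_day1: Schedule
    schedule_day2: Schedule

    @property
    def day1_labels(self) -> tuple[str, ...]:
        return self.schedule_day1.labels

    @property
    def day2_labels(self) -> tuple[str, ...]:
        return self.schedule_day2.labels


def run_lengths(trials: TypingSequence[str]) -> list[tuple[str, int]]:
    """Run-length encode a label sequence."""
    return [(lab, sum(1 for _ in grp)) for lab, grp in itertools.groupby(trials)]


@lru_cache(maxsize=1)
def all_valid_sequences() -> tuple[tuple[str, ...], ...]:
    """Enumerate all valid orderings of the key multiset (8!/2!^4 = 2520)."""
    base = sorted(KEYS * KEY_COPIES)
    return tuple(tuple(p) for p in multiset_permutations(base))


def _has_adjacent_repeat(items: TypingSequence[str]) -> bool:
    return any(a == b for a, b in zip(items, items[1:]))


def generate_sequence(
    rng: int | np.random.Generator,
    forbidden: Iterable[Sequence | tuple[str, ...]] = (),
    label: str = "A",
    forbid_adjacent_repeats: bool = False,
) -> Sequence:
    """Uniformly sample a valid sequence outside ``forbidden``.

    Deterministic given the seed / generator state.  Raises ``ValueError``
    if the forbidden set exhausts the (2520-element) space.
    """
    rng = _as_rng(rng)
    banned = {tuple(f.items) if isinstance(f, Sequence) else tuple(f) for f in forbidden}
    pool = np.array(sorted(KEYS * KEY_COPIES))
    for _ in range(300):  # rejection sampling; the space is rarely tight
        items = tuple(rng.permutation(pool).tolist())
        if items in banned:
            continue
        if forbid_adjacent_repeats and _has_adjacent_repeat(items):
            continue
        return Sequence(items=items, label=label)
    # fall back to explicit enumeration of the remaining space
    remaining = [
        s
        for s in all_valid_sequences()
        if s not in banned and not (forbid_adjacent_repeats and _has_adjacent_repeat(s))
    ]
    if not remaining:
        raise ValueError("sequence space exhausted by the forbidden set")
    idx = int(rng.integers(len(remaining)))
    return Sequence(items=remaining[idx], label=label)


def _interleave_labels(
    labels: TypingSequence[str],
    rng: np.random.Generator,
    run_length_cap: int,
) -> tuple[str, ...]:
    """Seeded random order of the 240-label multiset with bounded runs.

    Constructive sampler: at each position draw a label with probability
    proportional to its remaining count, excluding the label that would
    extend the current run past the cap; restart on a dead end (rare,
    only possible near the end of the stream).
    """
    n_labels = len(labels)
    for _ in range(1000):
        counts = [PRESENTATIONS_PER_SEQUENCE] * n_labels
        out: list[int] = []
        run_label, run_len = -1, 0
        ok = True
        for _pos in range(PRESENTATIONS_PER_SEQUENCE * n_labels):
            total = 0
            weights = [0] * n_labels
            for i in range(n_labels):
                if counts[i] == 0 or (i == run_label and run_len >= run_length_cap):
                    continue
                weights[i] = counts[i]
                total += weights[i]
            if total == 0:
                ok = False
                break
            u = rng.random() * total
            acc = 0.0
            pick = n_labels - 1
            for i in range(n_labels):
                acc += weights[i]
                if u < acc:
                    pick = i
                    break
            out.append(pick)
            counts[pick] -= 1
            if pick == run_label:
                run_len += 1
            else:
                run_label, run_len = pick, 1
        if ok:
            return tuple(labels[i] for i in out)
    raise RuntimeError("could not construct an interleaved schedule under the run-length cap")


def build_schedule(
    condition: str,
    labels: TypingSequence[str],
    rng: int | np.random.Generator,
    run_length_cap: int = 2,
    day: int = 1,
    experiment: str = "retention",
) -> Schedule:
    """Build a 240-trial schedule realizing ``condition`` over three labels.

    Blocked: the three 80-trial runs in a seeded random order.
    Interleaved: a seeded pseudo-random order with no run of identical
    adjacent labels longer than ``run_length_cap``.
    """
    labels = tuple(labels)
    if len(set(labels)) != len(labels):
        raise ValueError("sequence labels must be distinct")
    if len(labels) != N_SEQUENCES_PER_DAY:
        raise ValueError(f"expected {N_SEQUENCES_PER_DAY} labels, got {len(labels)}")
    rng = _as_rng(rng)
    if condition == "blocked":
        order = rng.permutation(len(labels))
        trials = tuple(
            itertools.chain.from_iterable(
                [labels[i]] * PRESENTATIONS_PER_SEQUENCE for i in order
            )
        )
        cap = None
    elif condition == "interleaved":
        trials = _interleave_labels(labels, rng, run_length_cap)
        cap = run_length_cap
    else:
        raise ValueError(f"unknown condition {condition!r}")
    return Schedule(condition=condition, day=day, trials=trials, experiment=experiment, run_length_cap=cap)


def counterbalanced_cells(n_participants: int, rng: np.random.Generator) -> list[tuple[str, str]]:
    """Assign cells in shuffled blocks of four so cell sizes differ by <= 1."""
    cells: list[tuple[str, str]] = []
    while len(cells) < n_participants:
        order = rng.permutation(len(CELLS))
        cells.extend(CELLS[i] for i in order)
    return cells[:n_participants]


def build_experiment_design(
    experiment: str,
    n_participants: int,
    rng_seed: int | np.random.Generator,
    run_length_cap: int = 2,
    forbid_adjacent_repeats: bool = False,
) -> list[ParticipantDesign]:
    """Generate the full counterbalanced two-day design for a cohort.

    Retention: Day-2 sequences are identical to Day-1's.  Transfer: Day 2
    presents three fresh sequences (labels D, E, F), disjoint from the
    Day-1 set, six unique sequences per participant.  No two participants
    share the same ordered set of sequences.
    """
    if experiment not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {experiment!r}")
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    rng = _as_rng(rng_seed)
    cells = counterbalanced_cells(n_participants, rng)
    used_sets: set[tuple[tuple[str, ...], ...]] = set()
    designs: list[ParticipantDesign] = []
    n_needed = 6 if experiment == "transfer" else 3
    all_labels = DAY1_LABELS + DAY2_NOVEL_LABELS if experiment == "transfer" else DAY1_LABELS
    for pidx in range(n_participants):
        training, testing = cells[pidx]
        pid = f"P{pidx + 1:03d}"
        # draw a participant-unique ordered set of sequences; within a
        # participant all sequences are mutually distinct
        for _ in range(200):
            seqs: list[Sequence] = []
            for j in range(n_needed):
                seqs.append(
                    generate_sequence(
                        rng,
                        forbidden=[s.items for s in seqs],
                        label=all_labels[j],
                        forbid_adjacent_repeats=forbid_adjacent_repeats,
                    )
                )
            key = tuple(s.items for s in seqs)
            if key not in used_sets:
                used_sets.add(key)
                break
        else:  # pragma: no cover - would need a cohort of thousands
            raise ValueError("could not find an unused sequence set for participant")
        sequences = {s.label: s for s in seqs}
        assignment = GroupAssignment(
            participant_id=pid,
            training_condition=training,
            testing_condition=testing,
            experiment=experiment,
        )
        day2_labels = DAY2_NOVEL_LABELS if experiment == "transfer" else DAY1_LABELS
        schedule_day1 = build_schedule(
            training, DAY1_LABELS, rng, run_length_cap, day=1, experiment=experiment
        )
        schedule_day2 = build_schedule(
            testing, day2_labels, rng, run_length_cap, day=2, experiment=experiment
        )
        designs.append(
            ParticipantDesign(
                assignment=assignment,
                sequences=sequences,
                schedule_day1=schedule_day1,
                schedule_day2=schedule_day2,
            )
        )
    return designs


def design_to_frame(designs: Iterable[ParticipantDesign]) -> pd.DataFrame:
    """Flatten a cohort design to the export schema (one row per cued item)."""
    rows = []
    for d in designs:
        a = d.assignment
        for schedule in (d.schedule_day1, d.schedule_day2):
            for trial_index, lab in enumerate(schedule.trials):
                seq = d.sequences[lab]
                for pos, key in enumerate(seq.items):
                    rows.append(
                        (
                            a.participant_id,
                            a.experiment,
                            a.training_condition,
                            a.testing_condition,
                            schedule.day,
                            trial_index,
                            lab,
                            pos,
                            key,
                        )
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "experiment",
            "training_condition",
            "testing_condition",
            "day",
            "trial_index",
            "sequence_label",
            "item_position",
            "target_key",
        ],
    )
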