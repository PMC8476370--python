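"""Free-recall scoring, Monte Carlo chance calibration, learner classification.

After the second session participants type every key sequence they think
they saw.  Each typed string is scored against the true sequences; the
mean fraction recalled (the "explicit score", 1 = perfect) times eight
gives items-per-sequence.  Chance level is calibrated by Monte Carlo:
random valid sequences are compared with large random comparison sets,
and the replicate means locate the chance band.  Under the positional
rule the analytic chance level is exactly 0.25 (two items per sequence):
at each position the probability that two independent valid sequences
agree is sum_k (2/8)^2 * 4 = 1/4.  Participants at or below roughly
three items per sequence are classed as implicit learners, four or more
as explicit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence as TypingSequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .design import KEYS, KEY_COPIES, SEQUENCE_LENGTH, Sequence

logger = logging.getLogger(__name__)

RULES = ("positional", "longest_run")

#: analytic expected positional similarity of two independent valid sequences
CHANCE_SIMILARITY = 0.25


@dataclass(frozen=True)
class ExplicitScore:
    """Per-participant recall score and implicit/explicit label."""

    per_sequence_fraction: tuple[float, ...]
    mean_score: float
    items_per_sequence: float
    learner_class: str

    @classmethod
    def from_fractions(
        cls, fractions: TypingSequence[float], cutoff_items: float = 3.0
    ) -> "ExplicitScore":
        fractions = tuple(float(f) for f in fractions)
        mean_score = float(np.mean(fractions))
        items = mean_score * SEQUENCE_LENGTH
        return cls(
            per_sequence_fraction=fractions,
            mean_score=mean_score,
            items_per_sequence=items,
            learner_class=classify_items(items, cutoff_items),
        )


@dataclass(frozen=True)
class ChanceCalibration:
    """Replicate means of the chance-level similarity simulation."""

    n_comparison: int
    n_reps: int
    rule: str
    replicate_means: np.ndarray
    band: tuple[float, float]
    chance_items: float

    @property
    def grand_mean(self) -> float:
        return float(np.mean(self.replicate_means))

    def to_dict(self) -> dict:
        return {
            "n_comparison": self.n_comparison,
            "n_reps": self.n_reps,
            "rule": self.rule,
            "grand_mean": self.grand_mean,
            "band_min": self.band[0],
            "band_max": self.band[1],
            "chance_items": self.chance_items,
        }


def _sanitize(recalled: str) -> str:
    cleaned = "".join(ch for ch in recalled.upper() if ch in KEYS)
    if cleaned != recalled.upper():
        logger.warning("dropping characters outside %s from recalled string %r", KEYS, recalled)
    return cleaned


def similarity(recalled: str, truth: Sequence | str, rule: str = "positional") -> float:
    """Fraction of the true sequence reproduced by a typed string.

    positional (default): fraction of positions j < min(8, len(recalled))
    where recalled[j] equals truth[j]; the denominator is always 8, so
    short answers can only lose credit.  longest_run: length of the
    longest contiguous run of positional matches, divided by 8.
    """
    if rule not in RULES:
        raise ValueError(f"unknown rule {rule!r}")
    truth_items = truth.items if isinstance(truth, Sequence) else tuple(truth)
    cleaned = _sanitize(recalled)
    if not cleaned:
        logger.info("empty recalled string scores 0")
        return 0.0
    upto = min(SEQUENCE_LENGTH, len(cleaned))
    matches = [cleaned[j] == truth_items[j] for j in range(upto)]
    if rule == "positional":
        return sum(matches) / SEQUENCE_LENGTH
    best = cur = 0
    for m in matches:
        cur = cur + 1 if m else 0
        best = max(best, cur)
    return best / SEQUENCE_LENGTH


def classify_items(items_per_sequence: float, cutoff_items: float = 3.0) -> str:
    """implicit iff items_per_sequence < cutoff_items + 1 (i.e. below 4)."""
    return "implicit" if items_per_sequence < cutoff_items + 1 else "explicit"


def classify_learner(score: ExplicitScore, cutoff_items: float = 3.0) -> str:
    return classify_items(score.items_per_sequence, cutoff_items)


def assignment_similarities(
    typed: TypingSequence[str],
    truths: TypingSequence[Sequence | str],
    rule: str = "positional",
) -> list[float]:
    """Per-truth similarity under the optimal one-to-one typed->truth pairing.

    Each typed string credits at most one true sequence; the pairing
    maximizes total similarity (solved exactly as a linear assignment
    problem).  Unmatched truths score 0.
    """
    fractions = [0.0] * len(truths)
    typed = [t for t in typed if _sanitize(t)]
    if not typed:
        return fractions
    sim = np.array([[similarity(t, s, rule) for s in truths] for t in typed])
    rows, cols = linear_sum_assignment(sim, maximize=True)
    for r, c in zip(rows, cols):
        fractions[c] = float(sim[r, c])
    return fractions


def score_recall(
    response,
    truths: TypingSequence[Sequence | str],
    rule: str = "positional",
    cutoff_items: float = 3.0,
) -> ExplicitScore:
    """Score one participant's typed recall against the true sequences.

    ``response`` is a RecallResponse (anything with ``typed_sequences``)
    or a plain list of typed strings.  With three truths (retention) the
    explicit score averages the three per-truth fractions.  With six
    truths (transfer: Day-1 plus Day-2 pools) the score is the mean of
    the best-matching three truths, keeping the construct items *per
    sequence* comparable across experiments.
    """
    typed = response if isinstance(response, (list, tuple)) else response.typed_sequences
    fractions = assignment_similarities(typed, truths, rule)
    if len(truths) > 3:
        fractions = sorted(fractions, reverse=True)[:3]
    return ExplicitScore.from_fractions(fractions, cutoff_items)


def random_valid_sequences(n: int, rng: np.random.Generator) -> np.ndarray:
    """n independent uniform valid sequences as an (n, 8) int array (key codes)."""
    base = np.repeat(np.arange(len(KEYS), dtype=np.int8), KEY_COPIES)
    tiled = np.broadcast_to(base, (n, SEQUENCE_LENGTH))
    order = np.argsort(rng.random((n, SEQUENCE_LENGTH)), axis=1)
    return np.take_along_axis(np.ascontiguousarray(tiled), order, axis=1)


def _pairwise_mean_similarity(tests: np.ndarray, comparison: np.ndarray, rule: str) -> np.ndarray:
    """Mean similarity of each test row against every comparison row."""
    if rule == "positional":
        # (n_test, n_comp, 8) equality, averaged over positions then comparisons
        eq = tests[:, None, :] == comparison[None, :, :]
        return eq.mean(axis=2).mean(axis=1)
    # longest_run, vectorized over the comparison set one test at a time
    out = np.empty(len(tests))
    for i, t in enumerate(tests):
        eq = comparison == t[None, :]
        best = np.zeros(len(comparison), dtype=np.int8)
        cur = np.zeros(len(comparison), dtype=np.int8)
        for j in range(SEQUENCE_LENGTH):
            cur = np.where(eq[:, j], cur + 1, 0)
            best = np.maximum(best, cur)
        out[i] = best.mean() / SEQUENCE_LENGTH
    return out


def calibrate_chance(
    n_comparison: int = 10_000,
    n_reps: int = 500,
    rule: str = "positional",
    rng_seed: int | np.random.Generator = 0,
) -> ChanceCalibration:
    """Monte Carlo chance calibration of the recall similarity score.

    Each replicate draws three fresh random test sequences and a fresh
    comparison set of ``n_comparison`` random sequences, computes each
    test sequence's mean similarity over the comparison set, and averages
    the three.  The band is the (min, max) of the replicate means and
    ``chance_items`` the band midpoint scaled to items per sequence.
    """
    if n_comparison < 1 or n_reps < 1:
        raise ValueError("n_comparison and n_reps must be >= 1")
    if rule not in RULES:
        raise ValueError(f"unknown rule {rule!r}")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    means = np.empty(n_reps)
    for rep in range(n_reps):
        tests = random_valid_sequences(3, rng)
        comparison = random_valid_sequences(n_comparison, rng)
        means[rep] = _pairwise_mean_similarity(tests, comparison, rule).mean()
    band = (float(means.min()), float(means.max()))
    return ChanceCalibration(
        n_comparison=n_comparison,
        n_reps=n_reps,
        rule=rule,
        replicate_means=means,
        band=band,
        chance_items=(band[0] + band[1]) / 2 * SEQUENCE_LENGTH,
    )
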