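"""Sequence RTs, accuracy, windows and difference scores."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_sequence_rt_frame
from srtt_ci.design import GroupAssignment
from srtt_ci.metrics import (
    accuracy,
    difference_scores,
    exclusion_flag,
    sequence_rts,
    sequence_rts_from_sim,
    window_mean,
)


def make_press_log(trials, participant_id="P001", day=1):
    """Per-press log from (label, press_rts, correct_flags) trial specs."""
    rows = []
    for idx, (lab, rts, oks) in enumerate(trials):
        for press, (rt, ok) in enumerate(zip(rts, oks)):
            rows.append((participant_id, day, idx, lab, press, "U", "U" if ok else "I", ok, rt))
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id", "day", "trial_index", "sequence_label",
            "press_index", "target_key", "response_key", "correct", "press_rt",
        ],
    )


class TestSequenceRts:
    def test_sums_and_correct_conjunction(self):
        log = make_press_log(
            [
                ("A", [0.25] * 8, [True] * 8),
                ("B", [0.25] * 8, [True] * 7 + [False]),
            ]
        )
        out = sequence_rts(log)
        assert out.loc[0, "rt_sum"] == pytest.approx(2.0)
        assert bool(out.loc[0, "correct"]) is True
        assert bool(out.loc[1, "correct"]) is False  # retained but flagged

    def test_malformed_trial_reported(self):
        log = make_press_log([("A", [0.25] * 8, [True] * 8)])
        broken = log.drop(index=3)
        with pytest.raises(ValueError, match="trial 0"):
            sequence_rts(broken)

    def test_full_day_has_240_records(self, one_participant_sim):
        out = sequence_rts(one_participant_sim.to_frame())
        assert (out.groupby("day").size() == 240).all()
        fast = sequence_rts_from_sim(one_participant_sim)
        pd.testing.assert_frame_equal(
            out.sort_values(["day", "trial_index"]).reset_index(drop=True)[fast.columns],
            fast,
            check_dtype=False,
        )


class TestAccuracy:
    def test_error_free_is_hundred_percent(self):
        log = make_press_log([("A", [0.25] * 8, [True] * 8)] * 5)
        assert accuracy(log, 1) == 100.0

    def test_per_press_definition(self):
        log = make_press_log([("A", [0.25] * 8, [True] * 7 + [False])] * 5)
        assert accuracy(log, 1) == pytest.approx(100 * 7 / 8)

    def test_exclusion_rule_either_day(self):
        assert exclusion_flag(79.9, 95.0)[0]
        assert exclusion_flag(95.0, 79.9)[0]
        assert not exclusion_flag(80.0, 80.0)[0]
        assert exclusion_flag(95.0, 99.0, threshold=96.0)[0]


class TestWindows:
    def test_constant_rts_any_window(self):
        trials = [("A", 2.0, True)] * 80 + [("B", 2.0, True)] * 80 + [("C", 2.0, True)] * 80
        df = make_sequence_rt_frame({1: trials})
        for cond in ("blocked", "interleaved"):
            for end in ("first", "last"):
                assert window_mean(df, cond, 1, end) == pytest.approx(2.0)

    def test_blocked_window_is_per_sequence_hand_computed(self):
        # block of A descending 3.0 -> 2.21, block of B constant 2.0, C constant 1.0
        a = [("A", 3.0 - 0.01 * i, True) for i in range(80)]
        b = [("B", 2.0, True)] * 80
        c = [("C", 1.0, True)] * 80
        df = make_sequence_rt_frame({1: a + b + c})
        last10_a = np.mean([3.0 - 0.01 * i for i in range(70, 80)])
        expected = (last10_a + 2.0 + 1.0) / 3
        assert window_mean(df, "blocked", 1, "last") == pytest.approx(expected)
        # the interleaved rule instead takes the literal last 30 trials (all C)
        assert window_mean(df, "interleaved", 1, "last") == pytest.approx(1.0)

    def test_windows_skip_error_trials(self):
        trials = [("A", 9.9, False)] * 5 + [("A", 2.0, True)] * 75
        trials += [("B", 2.0, True)] * 80 + [("C", 2.0, True)] * 80
        df = make_sequence_rt_frame({1: trials})
        assert window_mean(df, "blocked", 1, "first") == pytest.approx(2.0)

    def test_short_window_uses_available_trials(self, caplog):
        trials = [("A", 2.0, True)] * 4 + [("A", 4.0, False)] * 76
        trials += [("B", 2.0, True)] * 80 + [("C", 2.0, True)] * 80
        df = make_sequence_rt_frame({1: trials})
        with caplog.at_level("WARNING"):
            val = window_mean(df, "blocked", 1, "first")
        assert val == pytest.approx(2.0)
        assert any("correct trials" in r.message for r in caplog.records)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(0)
        trials = [(lab, float(rng.uniform(1, 3)), True) for lab in "ABC" * 80]
        df = make_sequence_rt_frame({1: trials})
        shuffled = df.sample(frac=1, random_state=1)
        for cond in ("blocked", "interleaved"):
            assert window_mean(df, cond, 1, "last") == pytest.approx(
                window_mean(shuffled, cond, 1, "last")
            )


class TestDifferenceScores:
    def assignment(self, training="interleaved", testing="interleaved", experiment="retention"):
        return GroupAssignment("P001", training, testing, experiment)

    def test_retention_sign_convention(self):
        day1 = [("A", 3.0, True)] * 180 + [("A", 2.0, True)] * 60
        day2 = [("A", 1.8, True)] * 240
        df = make_sequence_rt_frame({1: day1, 2: day2})
        scores = {s.kind: s for s in difference_scores(df, self.assignment())}
        assert scores["retention"].value == pytest.approx(-0.2)  # improvement
        assert scores["learning"].value == pytest.approx(-1.0)

    def test_equal_windows_mean_perfect_retention(self):
        day = [("A", 2.0, True)] * 240
        df = make_sequence_rt_frame({1: day, 2: day})
        scores = {s.kind: s.value for s in difference_scores(df, self.assignment())}
        assert scores["retention"] == pytest.approx(0.0)

    def test_transfer_uses_day1_first_window(self):
        day1 = [("A", 3.0, True)] * 30 + [("A", 2.0, True)] * 210
        day2 = [("D", 2.5, True)] * 240
        df = make_sequence_rt_frame({1: day1, 2: day2})
        scores = {
            s.kind: s.value
            for s in difference_scores(df, self.assignment(experiment="transfer"))
        }
        assert scores["transfer"] == pytest.approx(-0.5)
        assert "retention" not in scores

    def test_day_specific_constant_shifts_retention_only(self):
        rng = np.random.default_rng(2)
        day1 = [("A", float(rng.uniform(1.5, 2.5)), True) for _ in range(240)]
        day2 = [("A", float(rng.uniform(1.5, 2.5)), True) for _ in range(240)]
        df = make_sequence_rt_frame({1: day1, 2: day2})
        base = {s.kind: s.value for s in difference_scores(df, self.assignment())}
        shifted = df.copy()
        shifted.loc[shifted["day"] == 2, "rt_sum"] += 0.7
        out = {s.kind: s.value for s in difference_scores(shifted, self.assignment())}
        assert out["retention"] == pytest.approx(base["retention"] + 0.7)
        assert out["learning"] == pytest.approx(base["learning"])

    def test_mixed_design_uses_each_days_condition(self):
        """Day-1 windows follow training rule, Day-2 windows testing rule."""
        # Day 1 blocked: first 10 of each sequence; Day 2 interleaved: first 30
        a = [("A", 2.0, True)] * 80
        b = [("B", 4.0, True)] * 80
        c = [("C", 6.0, True)] * 80
        day2 = [("A", 5.0, True)] * 30 + [("B", 1.0, True)] * 90 + [("C", 1.0, True)] * 120
        df = make_sequence_rt_frame({1: a + b + c, 2: day2})
        scores = {
            s.kind: s.value
            for s in difference_scores(
                df, self.assignment(training="blocked", testing="interleaved")
            )
        }
        # retention = mean(first 30 of Day 2) - mean(last 10 per sequence Day 1)
        assert scores["retention"] == pytest.approx(5.0 - 4.0)
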