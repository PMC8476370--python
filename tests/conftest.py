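import numpy as np
import pandas as pd
import pytest

from srtt_ci.design import build_experiment_design
from srtt_ci.simulate import ParticipantParams, simulate_cohort, simulate_participant


@pytest.fixture(scope="session")
def small_retention_cohort():
    """A small paper-like retention cohort shared across tests."""
    return simulate_cohort("retention", 3, "paper-like", rng_seed=1234)


@pytest.fixture(scope="session")
def one_participant_sim():
    """A single deterministic error-free participant with known parameters."""
    design = build_experiment_design("retention", 1, rng_seed=7)[0]
    params = ParticipantParams(
        base_press_rt=0.30,
        general_gain=0.06,
        general_tau=50.0,
        seq_gain=0.05,
        seq_tau=30.0,
        switch_cost=0.02,
        press_noise_sd=0.02,
        press_error_prob=0.0,
        explicit_k=0,
    )
    return simulate_participant(design, params, rng_seed=11)


def make_sequence_rt_frame(day_values: dict[int, list[tuple[str, float, bool]]],
                           participant_id: str = "P001") -> pd.DataFrame:
    """Build a per-trial sequence-RT frame from (label, rt_sum, correct) lists."""
    rows = []
    for day, trials in day_values.items():
        for idx, (lab, rt, ok) in enumerate(trials):
            rows.append((participant_id, day, idx, lab, rt, ok))
    return pd.DataFrame(
        rows,
        columns=["participant_id", "day", "trial_index", "sequence_label", "rt_sum", "correct"],
    )
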