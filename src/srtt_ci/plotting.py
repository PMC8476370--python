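"""Small plotting helper (not contract-bound): binned learning curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_learning_curves(
    seq_df: pd.DataFrame, path: str | Path, bin_size: int = 20
) -> None:
    """Mean correct-trial sequence RT per bin of trials, one panel per day."""
    ok = seq_df[seq_df["correct"]].copy()
    ok["bin"] = ok["trial_index"] // bin_size
    days = sorted(ok["day"].unique())
    fig, axes = plt.subplots(1, len(days), figsize=(5 * len(days), 3.5), sharey=True)
    if len(days) == 1:
        axes = [axes]
    for ax, day in zip(axes, days):
        sub = ok[ok["day"] == day]
        curve = sub.groupby("bin")["rt_sum"].mean()
        ax.plot(curve.index * bin_size, curve.to_numpy(), marker="o", ms=3)
        ax.set_title(f"Day {day}")
        ax.set_xlabel("trial")
    axes[0].set_ylabel("sequence RT (s)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
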