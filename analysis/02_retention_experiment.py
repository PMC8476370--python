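#!/usr/bin/env python
"""Retention experiment on a simulated paper-like cohort (20 per cell).

Runs the full pipeline -- design, simulation, exclusion, recall scoring,
learner classification, trend tests and the ANOVA/ANCOVA battery -- and
writes the report bundle to results/retention/.

Finding: interleaved-trained cells (II, IB) carry negative retention
difference scores (performance maintained or improved overnight) while
blocked-trained cells are positive, most strongly BI; the testing-day
trend test is significantly decreasing in every cell except BI.  This is
the contextual-interference signature the synthetic cohort is built to
carry, recovered end to end by the analysis chain.
"""

from pathlib import Path

from srtt_ci.pipeline import RunConfig, run_experiment

OUT = Path(__file__).resolve().parents[1] / "results" / "retention"


def main() -> None:
    cfg = RunConfig(
        experiment="retention",
        preset="paper-like",
        n_per_cell=20,
        seed=20260926,
        mc_comparisons=2_000,
        mc_reps=200,
        out_dir=str(OUT),
    )
    bundle = run_experiment(cfg)
    print("learner counts by cell:")
    print(bundle.learner_counts.to_string())
    print("\nretention difference scores by cell (s):")
    print(bundle.score_table.round(3).to_string(index=False))
    print("\ntesting-day Mann-Kendall trends:")
    print(bundle.trend_table[bundle.trend_table["day"] == "2"].round(4).to_string(index=False))
    anova = [r for r in bundle.stat_results if r.test_name == "factorial_anova"]
    print("\nfactorial ANOVA on retention scores:")
    for r in anova:
        print(f"  {r.term}: F{tuple(int(v) for v in r.df)} = {r.statistic:.2f}, "
              f"p = {r.p_value:.4g}, eta^2 = {r.effect_sizes['eta_sq']:.3f}")
    print(f"\nbundle written to {OUT}")


if __name__ == "__main__":
    main()
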