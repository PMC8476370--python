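# Methods

## Scope

The package implements the complete computational chain of a two-day
SRTT contextual-interference study: experimental-design generation, a
generative stand-in for human participants, free-recall scoring with
Monte Carlo chance calibration, the windowed difference-score metrics,
and the statistical battery.  No human data ship with it; everything is
validated on synthetic cohorts with known generative parameters, plus
analytic and brute-force oracles.

## Design generation

Valid sequences are the 2520 orderings of the multiset
{U,U,I,I,O,O,P,P}; `generate_sequence` samples them uniformly by
rejection from random permutations, falling back to explicit
enumeration when a forbidden set makes the space tight.  Blocked
schedules randomize the order of the three 80-trial runs per
participant-day.  Interleaved schedules are a seeded pseudo-random
order of the 240-label multiset under a **run-length cap of 2**
(configurable): the published fragment of an interleaved stream shows
no long runs, and a cap keeps the condition high-interference.  The cap
is enforced constructively — each label is drawn with probability
proportional to its remaining count, excluding the label that would
break the cap, with a restart on the (rare) dead end — because a
uniform shuffle of 240 labels essentially never satisfies a cap of 2,
so rejection sampling of whole shuffles is infeasible.  Note the cap
raises the switch rate to ≈0.75 rather than the 2/3 of an unconstrained
shuffle.

Group assignment cycles through the four training/testing cells in
shuffled blocks of four, keeping cell sizes within one of each other.
No two participants receive the same ordered sequence set; individual
sequences may recur across participants.  Sequence boundaries exist
only in metadata — the stimulus stream is a flat list of cued keys.

## Generative model of a participant

Per-press RT is a baseline plus three exponentially decaying components
plus additive costs, truncated at a floor (defaults in parentheses):

    rt = max(floor, base                                   (0.30 s, floor 0.15 s)
                    + G  · exp(−t/τ_g)                     (nonspecific practice)
                    + S  · exp(−e/τ_s)                     (sequence-specific)
                    + W  · exp(−d/τ_w)                     (session warm-up)
                    + c_switch · [sequence switch]
                    + c_consol · [Day 2]
                    + N(0, σ))                             (σ = 0.09 s)

with t the cumulative trial index, e the prior exposures to the trial's
sequence, d the within-session trial index.  Errors are independent per
press with a condition-dependent probability; a wrong press is uniform
over the three other keys.  Free recall reproduces the first
`explicit_k` items of each relevant sequence and completes the string
with a random permutation of the remaining multiset, so recall grades
continuously from chance-level (k = 0) to perfect (k = 8).

Two mechanisms beyond the minimal model were needed to realize the
published result shape and are deliberate modeling choices:

* **Session warm-up (W, τ_w).**  Without a session-specific component
  the exponential terms are nearly flat by Day 2 and no cell can show a
  significant testing-day trend.  A warm-up that restarts each session
  supplies the within-session improvement seen on both days.
* **Day-2 learning suppression (`day2_learning` ∈ [0, 1]).**  A scale
  on how far the decay indices advance during Day 2.  At 0 the
  participant performs at their end-of-training level all day — the
  behavior of blocked-trained participants facing interleaved material,
  which produces both the flat BI testing-day trend and the BI-specific
  retention/transfer deficit.

Truncation at the floor is used rather than resampling; no post-error
slowing is modeled by default (an additive post-error cost is
available).

## Cohort presets

Presets fix parameters per training/testing cell; they are the study
conditions, not tuning knobs.

* **null** — all learning terms, costs and offsets zero: RT is noise
  around the baseline, error rate 5% everywhere.  Any systematic
  difference-score effect would be an artifact of the analysis chain.
  A flat mean is required for a genuine null because the blocked and
  interleaved window definitions sample different trial indices: with
  any shared learning curve the two window rules have different
  expectations, which is a property of the windows, not a bias of the
  tests.
* **paper-like** (retention) — blocked training expresses sequence
  learning fast (τ_s = 25 exposures) but consolidates poorly overnight
  (positive offset) and pays a high Day-2 switch cost with
  `day2_learning = 0` in the BI cell; interleaved training expresses
  slowly (τ_s = 400), consolidates (negative offset), and is robust to
  testing condition.  Per-press error probabilities follow the reported
  accuracy ranges (92–96%, interleaved less accurate on Day 1).
  Explicit recall ability `explicit_k` is binomial with a higher rate
  after blocked training, yielding both learner classes.
* **transfer-like** — same acquisition structure; overnight offsets
  represent consolidation of general skill (negative for both training
  conditions, larger after interleaving) because sequence-specific
  knowledge is irrelevant to novel sequences; the BI cell again gets
  `day2_learning = 0` plus the high switch cost, netting ≈0 transfer.

Preset constants were derived from the closed-form window expectations
of the model so that the per-cell signs, orderings and trend patterns
of the two experiments hold with wide margins, then verified by
simulation.  Magnitudes are in the right range but are not calibrated
to the published group means — trial-level RT distributions for this
paradigm are not publicly available, so only the qualitative shape is a
modeling target.

## Recall scoring and chance calibration

The default similarity rule is **positional**: the fraction of
positions (denominator always 8) at which the typed string matches the
true sequence; typed strings are truncated/padded implicitly by
comparing up to position 8.  This rule is used because it reproduces
the analytic chance level 0.25 that anchors the implicit/explicit
cutoff; a **longest-run** rule (longest contiguous matching run / 8) is
available as an alternative.  Typed strings are matched to truths by an
exact maximum-total-similarity one-to-one assignment (Hungarian
algorithm), so one typed sequence cannot credit several truths.  In the
transfer design recall spans six truths; the score averages the
best-matching three so that items-per-sequence remains comparable, and
the choice is recorded in the output.  Classification: implicit iff
items-per-sequence < 4 (cutoff configurable).

Chance calibration draws, per replicate, three fresh test sequences and
a fresh comparison set, and records the mean similarity.  The scaled
default (10⁴ comparisons × 500 replicates) runs in seconds and brackets
the analytic 0.25 tightly; the band is reported as an envelope (min,
max), and containment — not distributional shape — is the check, since
the spread of the original report at the million-comparison scale
exceeds sampling error under any per-position rule.

## Metrics

Windows are taken over **correct trials only** (the original analysis
used only accurate sequences; whether its windows skipped error trials
when counting "last ten" is unstated — this reading is an assumption).
If fewer correct trials than the window exist, all available are used
with a warning; empty windows propagate as missing values.  In mixed
cells each day's window follows that day's own condition rule, since
the day's schedule defines what "per sequence" means.  Accuracy is
per key press (the reported percentages are consistent with that
reading); per-sequence accuracy is also exposed.  All times are
seconds; millisecond inputs convert at ingest.

## Statistics

* Mann-Kendall: exhaustive pair counting for S, tie-corrected variance,
  continuity-corrected normal approximation; tau-b normalization (the
  time axis is untied).  Group-level trend tables run the test on the
  per-trial cell-mean RT series of correct trials (240 points).
* t tests: pooled variance for the two-sample test; Cohen's d from the
  pooled (or sample) SD.  Zero-variance inputs raise.
* Mann-Whitney U: asymptotic with tie correction and continuity.
* ANOVA/ANCOVA: Type III sums of squares with sum-to-zero effect coding
  (Type II/I by flag), the convention that handles the unbalanced cells
  created by post-hoc learner sorting.  Both classical and partial η²
  are emitted, labeled, since reports rarely say which is meant.
  Simple effects use the within-level error term (a one-way ANOVA on
  the subset); the error-term bookkeeping of published simple-effects
  F(1) values is underdetermined, so the package documents its choice.
  Tukey pairwise contrasts use the Tukey-Kramer adjustment for unequal
  n.  All tests are two-sided.

## Operating characteristics and problem sizes

`studies.type_i_error_rate` (500 null cohorts of 15 per cell) confirms
the training main effect rejects at the nominal 5% level;
`studies.pattern_recovery_rate` (100 paper-like cohorts of 20 per cell)
confirms the retention sign pattern and the BI-only flat testing-day
trend are recovered in ≈100% of replications.  These sizes keep each
study under about a minute on one CPU while leaving the binomial error
of the estimated rates small against the bands being checked.

## What the synthetic cohorts do and do not show

The generator reproduces the qualitative structure the analysis chain
assumes: monotone speed-up, faster blocked acquisition, condition-
dependent consolidation, switch costs, accuracy in the 92–96% band, and
recall from chance to perfect.  It does **not** model trial-level RT
distributions (right skew, lapses), post-error slowing (off by
default), sleep variation, fatigue, or participant dropout.  Passing
tests therefore certify the pipeline — that the metrics, scoring and
tests recover known generative structure and stay calibrated under the
null — not any claim about human data.  Published group means and F
statistics depend on the unavailable raw data and are deliberately not
reproduction targets.

## Known limitations

* Exact small-sample tables for U and the Mann-Kendall test are not
  implemented; both use corrected normal approximations, adequate at
  the 240-trial and ≥15-per-cell sizes used here.
* The recall assignment treats each typed string as one candidate
  sequence; segmentation of free-form typing into candidate sequences
  is assumed done upstream (the questionnaire collects one string per
  line).
* Whether the original interleaved orders were constrained beyond
  randomization is unknown; the run-length cap is this package's
  operationalization.
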