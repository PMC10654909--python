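# Methods

This note documents the statistical procedures, the generative model
behind the synthetic cohort, the numerical conventions, and the design
choices made where the conventions of the field leave room.

## Alignment and the 1-second grid

Sleep stages are scored per epoch (30 s for PSG; devices use 15–60 s),
and the two scorers' epoch boundaries are generally out of phase. All
epoch-by-epoch statistics are therefore computed on a common 1-second
grid: each epoch's label is repeated for its duration and streams are
compared second by second. Alignment to the reference window follows
three rules: device seconds before the PSG start are discarded; a device
that starts late is scored wake until its measurement begins; the
endpoint is aligned with the PSG end. A device that *stops* early is the
one case the rules above do not determine; we mirror the head rule — the
unobserved tail is scored wake, counted in `padded_tail_seconds`, and a
warning is emitted — so that every aligned pair spans exactly the
reference's time in bed. Start times are floored to whole seconds; 1 s is
the finest resolution anywhere in the pipeline.

Consequence worth knowing: wake-padding is a *modelling assertion* (the
person was presumably awake before the device began), and it counts
toward the device's wake row like any observed second.

## Agreement statistics

Everything derives from the 4×4 per-second count matrix (reference rows,
device columns). Per-stage metrics are one-vs-rest: sensitivity
TP/(TP+FN), specificity TN/(TN+FP), F1 = 2TP/(2TP+FP+FN). Macro F1 is
the unweighted mean of the four stage F1s; weighted F1 weights by
reference-row support; kappa is plain (unweighted) Cohen's kappa with
chance agreement from the marginal products. Degenerate cases are flagged
rather than silently zeroed: zero reference support makes sensitivity
NaN (`sensitivity_defined=False`); a stage absent from both positive sets
gets F1 = 0 with `f1_degenerate=True` (this keeps macro F1 computable on
short or stage-poor sessions while surfacing the issue); two constant,
identical raters make kappa undefined (`kappa_defined=False`).

Device-level metrics pool the confusion counts over all of a device's
sessions before computing metrics (`pooled` mode, the default — this
weights every compared second equally and matches how headline tables of
epoch-level studies are built). A `per_participant` mode computes metrics
per participant and averages them; the two genuinely differ because the
metrics are nonlinear in the counts, and both are exposed everywhere,
including the subgroup tables, since published per-site columns do not
always state which was used.

## Sleep measures

Computed in integer seconds and converted to hours/minutes/percent only
for reporting. Sleep onset is the first non-wake second (the "first
epoch of any sleep" convention); WASO counts all wake from onset to the
end of the record (no final-awakening truncation), which is the simplest
convention under which TIB = SOL + TST + WASO holds exactly — an identity
the property tests enforce on random hypnograms. REM latency is measured
from sleep onset by default; a `rem_latency_reference="start"` option
measures from the record start instead, since published tables do not
always say which was meant. Nights without sleep or without REM return
flagged-absent values, never silent zeros.

## Concordance

Bland–Altman differences are device − reference, so positive bias means
the device overestimates. `sd_diff` uses the sample (n−1) denominator;
limits of agreement are bias ± 1.96·SD. Proportional bias is the Pearson
correlation between pair means and differences with its two-sided
t-distribution p-value; it is flagged undefined below n = 3 or when
either spread is zero. Sessions missing a measure (no REM, no sleep) are
dropped pairwise per measure with the dropped count logged. The t test
defaults to Welch (two-site demographics have visibly unequal variances);
the pooled variant exists for strict replication. The Fisher exact test
is the standard two-sided hypergeometric sum, delegated to scipy and
cross-checked in the tests against exhaustive enumeration of all tables
with margins ≤ 15.

## Reporting conventions

Printed tables round half-up: 4 decimals for metrics and subgroup means,
3 for top-k stage averages. Internally everything is kept at full
precision; rounding happens at serialization and in the explicitly
"reporting-rounded" aggregation helpers. Site averages and subgroup
column means are unweighted over devices (not weighted by n) — the only
convention under which the published cross-table aggregates are exactly
recoverable from the published per-device values. Subgroup thresholds
default to AHI 15, SE 85 % (PSG-derived), BMI 25, with membership ≤ vs >.
Rank-heatmap rows map each device's best measure to 1 and worst to 0;
constant rows are flagged NaN.

## The synthetic cohort

The generator emulates the *study conditions* — not sleep physiology.

**Reference nights.** A night is a first-order Markov chain over
(wake, light, deep, REM) at 30-s epochs, started in wake, with length
drawn from TIB ~ N(7.24 h, 0.92 h) truncated at 1 h. The default chain
is a "sticky resampling" chain, `P = (1 − r) I + 1 πᵀ r`: persist with
probability 1 − r, otherwise redraw from π. This family has exact
stationary distribution π for any r, and the first wake dwell (the sleep
onset latency) is geometric with mean 1/(r(1 − π_W)). Calibration
(`scripts/calibrate_architecture.py`, run once, offline) fixes r from the
target mean SOL of 0.27 h, sets π_deep = 0.108 (the published deep-stage
share of epochs) and π_REM = 0.168, and bisects π_W until the simulated
cohort mean WASO equals 1.15 h, giving π_W ≈ 0.1697. The resulting cohort
means — TIB 7.24 h, TST 5.83 h, SOL 0.27 h, WASO 1.15 h, SE ≈ 80.4 % —
match the published cohort to within sampling error. The two sites use
their own TIB distributions (8.01 ± 0.31 h vs 6.49 ± 0.66 h), which also
reproduces the direction of the published site differences in WASO.

What this chain does *not* model: ultradian sleep cycles (REM latency is
exponential-ish rather than ~90 min), between-subject frailty (the
per-night SE spread is ≈ 9 points vs ≈ 17 in the real cohort), and any
dependence of architecture on age, BMI or AHI. Passing recovery tests
therefore demonstrates correctness of the *pipeline arithmetic* under
known truth, not realism of the nights.

**Device readings.** Each device epoch's label is drawn from a
stage-conditional emission matrix given the reference stage at the
epoch's midpoint (wake outside the reference window); errors are
conditionally independent across epochs — enough to exercise every
metric; temporally correlated errors are a documented extension point.
Devices get their own epoch duration and start offset (both varied in
the default roster to exercise resegmentation and alignment), and a
per-session dropout probability. The default emission archetypes follow
the misclassification narratives of the published confusion matrices —
wearables: wake→light; nearables: REM→light and weak deep sensitivity;
airables: light↔deep, with one deep-dominated device reporting ~60 % of
the night as deep — and are illustrative, not fitted, since the study
never tabulated its per-device confusion matrices numerically.

**Cohort structure.** Two sites (37 + 38 participants) with the
published sex ratios and age/BMI moments (normal, clipped to the
recruitment range) and AHI from a gamma distribution matching each
site's mean and SD. Participants alternate between device groups A and
B; devices that interfere (shared radar band; more than two watches) are
declared as conflict pairs and may never share a group — a configuration
with a violated conflict is rejected. Randomness is split per
(participant, device) via `SeedSequence` spawn keys, so enlarging the
roster never perturbs existing sessions, and the whole cohort is
byte-reproducible from its seed.

## Problem sizes used in checks

The recovery and calibration checks run at sizes chosen to make their
tolerances meaningful at interactive cost: emission recovery pools 30
nights of ~8 h (≈ 860 k compared seconds, binomial SE per cell well below
the 0.02 tolerance); the calibrated-architecture check uses 500 nights
against a two-standard-error band; the t-test calibration uses 5 000
null replicates at the study's 37/38 group sizes; oracle equivalence
uses 1 000 random aligned pairs up to 10 000 s against a pure-python
tally oracle at 1e−12.

## Known limitations

* Published device-level metrics are reproduced as *inputs* (the raw
  recordings were never deposited); only aggregates over them are
  recomputed.
* The generator's stage dynamics are deliberately minimal (see above);
  conclusions about real-device performance cannot be drawn from it.
* One published narrative claim is internally inconsistent with its own
  table: the table's BMI-split differences put Withings (0.0796) above
  Galaxy Watch 5 (0.0785), while the text names Galaxy Watch 5 as the
  largest. The package reports what the table implies.
* AUROC-style probabilistic metrics are out of scope: label streams
  carry no per-stage probabilities.
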