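"""Reproduce the published cross-table aggregates from the printed values.

The study's raw recordings were never deposited, so per-device metrics
are taken as printed; every aggregate over them - per-site averages,
subgroup column means, stage-winner margins, top-5 stage averages - is
recomputed here through the cohort-report operations.
"""

from cstval.benchmark import DEVICE_TABLE, STAGE_TABLE, SUBGROUP_TABLE, TOP5_DEVICES
from cstval.report import (
    site_average_macro_f1,
    stage_margin,
    subgroup_column_means,
    subgroup_side_differences,
    top_k_stage_average,
)

print("per-site average macro F1:")
print("  SNUBH:", site_average_macro_f1(DEVICE_TABLE["macro_f1_snubh"]))
print("  CLC  :", site_average_macro_f1(DEVICE_TABLE["macro_f1_clc"]))

means = subgroup_column_means(SUBGROUP_TABLE)
print("subgroup macro-F1 column means:")
for col in SUBGROUP_TABLE.columns:
    print(f"  {col:>10}: {means[col]}")

wake = stage_margin(STAGE_TABLE["wake_f1"])
rem = stage_margin(STAGE_TABLE["rem_f1"])
print(f"wake-stage winner: {wake.top_device} over {wake.runner_up} "
      f"by {wake.margin}")
print(f"REM-stage winner : {rem.top_device} over {rem.runner_up} "
      f"by {rem.margin}")

print("top-5 devices:", ", ".join(TOP5_DEVICES))
print("  average wake F1:", top_k_stage_average(STAGE_TABLE["wake_f1"], TOP5_DEVICES))
print("  average deep F1:", top_k_stage_average(STAGE_TABLE["deep_f1"], TOP5_DEVICES))
print("  average REM  F1:", top_k_stage_average(STAGE_TABLE["rem_f1"], TOP5_DEVICES))

diffs = subgroup_side_differences(SUBGROUP_TABLE)
print("largest subgroup swing per variable:")
for var in diffs.columns:
    print(f"  {var:>6}: {diffs[var].idxmax()} ({diffs[var].max():.4f})")
# REM is the easiest stage for good trackers (distinctive heart-rate and
# breathing irregularity); the sex split barely moves the average at all.
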