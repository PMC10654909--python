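"""Published per-device benchmark values from a two-site validation study.

A prospective two-site validation cohort (75 participants; a tertiary
hospital, SNUBH, and a primary sleep clinic, CLC) compared 11 consumer
sleep trackers — 5 wearables, 3 nearables and 3 airables — against in-lab
polysomnography.  The tables below carry the study's printed per-device
epoch-by-epoch results: the four-stage summary metrics with per-site macro
F1 (``DEVICE_TABLE``), the one-vs-rest stage metrics (``STAGE_TABLE``),
the subgroup macro-F1 matrix (``SUBGROUP_TABLE``), and the participant
demographics of the two sites (``DEMOGRAPHICS_TABLE``).

They serve two purposes:

* as real inputs for the aggregation routines in :mod:`cstval.report`
  (site averages, stage margins, subgroup column means are all exact
  arithmetic on these printed values);
* as calibration targets and archetypes for :mod:`cstval.simulate`.

The raw recordings behind these numbers were never deposited, so
device-level metrics themselves are not recomputable — only the
aggregates over them are.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = [
    "DEVICE_TABLE",
    "STAGE_TABLE",
    "SUBGROUP_TABLE",
    "DEMOGRAPHICS_TABLE",
    "SITES",
    "TOP5_DEVICES",
]

SITES = ("SNUBH", "CLC")

_DEVICE_CSV = """\
device_id,device_class,n,accuracy,weighted_f1,kappa,macro_f1,macro_f1_snubh,macro_f1_clc
SleepRoutine,airable,67,0.7106,0.7166,0.5565,0.6863,0.7188,0.6551
SleepScore,airable,38,0.4329,0.4472,0.2065,0.4049,0.4408,0.3094
Pillow,airable,74,0.2830,0.2906,0.0741,0.2588,0.2604,0.2564
Withings Sleep Tracking Mat,nearable,75,0.4921,0.5007,0.2455,0.4496,0.4205,0.4837
Google Nest Hub 2,nearable,33,0.4121,0.4089,0.0644,0.3009,0.2676,0.3299
Amazon Halo Rise,nearable,28,0.6634,0.6706,0.4807,0.6242,0.6231,0.6031
Google Pixel Watch,wearable,30,0.6355,0.6143,0.4044,0.5669,0.5381,0.5925
Galaxy Watch 5,wearable,22,0.6494,0.6499,0.4177,0.5761,0.6261,0.5651
Fitbit Sense 2,wearable,26,0.6464,0.6296,0.4185,0.5814,0.5130,0.6268
Apple Watch 8,wearable,26,0.5640,0.5731,0.2976,0.4910,0.5436,0.4203
Oura Ring 3,wearable,53,0.5427,0.5518,0.3492,0.5186,0.5187,0.5211
"""

_STAGE_CSV = """\
device_id,wake_f1,wake_sensitivity,wake_specificity,light_f1,light_sensitivity,light_specificity,deep_f1,deep_sensitivity,deep_specificity,rem_f1,rem_sensitivity,rem_specificity
SleepRoutine,0.7065,0.7246,0.9269,0.7436,0.7054,0.7665,0.5355,0.6712,0.8973,0.7596,0.7394,0.9609
SleepScore,0.4057,0.3665,0.8696,0.5147,0.4355,0.7272,0.3574,0.5247,0.8264,0.3418,0.4587,0.7895
Pillow,0.2828,0.1934,0.9572,0.3409,0.2490,0.7534,0.2673,0.8594,0.4449,0.1440,0.1140,0.9126
Withings Sleep Tracking Mat,0.4419,0.4172,0.8854,0.5764,0.5328,0.6336,0.3800,0.5633,0.8270,0.4001,0.3964,0.8906
Google Nest Hub 2,0.3296,0.3068,0.8649,0.5619,0.5772,0.4518,0.1245,0.1308,0.8883,0.1876,0.1805,0.8514
Amazon Halo Rise,0.5967,0.6612,0.8921,0.7142,0.6609,0.7484,0.4575,0.5467,0.9018,0.7283,0.7490,0.9401
Google Pixel Watch,0.3456,0.2277,0.9784,0.7150,0.7657,0.5620,0.5922,0.6937,0.9290,0.6146,0.6548,0.9029
Galaxy Watch 5,0.4755,0.4814,0.9104,0.7346,0.7280,0.6412,0.4963,0.4752,0.9481,0.5982,0.6265,0.9058
Fitbit Sense 2,0.3807,0.2714,0.9602,0.7262,0.7734,0.5727,0.5564,0.6710,0.9247,0.6623,0.6812,0.9297
Apple Watch 8,0.5493,0.4481,0.9624,0.6680,0.6649,0.5737,0.3073,0.4130,0.8412,0.4394,0.4276,0.9070
Oura Ring 3,0.4527,0.3822,0.9264,0.5953,0.5072,0.7630,0.4272,0.7784,0.7974,0.5993,0.7118,0.8716
"""

_SUBGROUP_CSV = """\
device_id,ahi<=15,ahi>15,se_pct<=85,se_pct>85,bmi<=25,bmi>25,male,female
SleepRoutine,0.6536,0.7320,0.6971,0.6490,0.6840,0.6889,0.7137,0.6568
SleepScore,0.3636,0.4565,0.4107,0.3808,0.4118,0.3937,0.4431,0.3559
Pillow,0.2602,0.2567,0.2472,0.2567,0.2601,0.2548,0.2670,0.2446
Withings Sleep Tracking Mat,0.4644,0.4225,0.3766,0.4653,0.4760,0.3964,0.4587,0.4355
Google Nest Hub 2,0.3000,0.3059,0.3115,0.2762,0.3209,0.2517,0.2889,0.3059
Amazon Halo Rise,0.6160,0.6389,0.6297,0.5857,0.6414,0.5801,0.6075,0.6491
Google Pixel Watch,0.5670,0.5626,0.5035,0.6102,0.5653,0.5791,0.5235,0.5956
Galaxy Watch 5,0.5701,0.5790,0.6029,0.5547,0.5521,0.6306,0.5655,0.5867
Fitbit Sense 2,0.5839,0.5753,0.5325,0.6090,0.5910,0.5541,0.5320,0.6129
Apple Watch 8,0.4861,0.4950,0.4326,0.4804,0.5093,0.4561,0.5263,0.4414
Oura Ring 3,0.5302,0.5021,0.4882,0.5245,0.5354,0.4830,0.4926,0.5405
"""

# site demographics and polysomnography sleep measures: mean (sd), plus
# male counts out of n — the generator's calibration targets
_DEMOGRAPHICS_CSV = """\
variable,total_mean,total_sd,snubh_mean,snubh_sd,clc_mean,clc_sd
age_y,43.59,14.10,53.49,11.96,33.95,8.07
bmi,23.90,4.07,24.64,4.07,23.18,3.98
tib_h,7.24,0.92,8.01,0.31,6.49,0.66
tst_h,5.82,1.33,6.26,1.2,5.40,1.33
sol_h,0.27,0.37,0.27,0.38,0.26,0.38
waso_h,1.15,1.2,1.48,1.22,0.83,1.23
se_pct,81.00,17.5,78.40,15.54,83.54,19.1
ahi,18.18,20.39,26.56,24.25,10.02,10.99
"""

DEVICE_TABLE: pd.DataFrame = pd.read_csv(
    io.StringIO(_DEVICE_CSV), index_col="device_id"
)
STAGE_TABLE: pd.DataFrame = pd.read_csv(
    io.StringIO(_STAGE_CSV), index_col="device_id"
)
SUBGROUP_TABLE: pd.DataFrame = pd.read_csv(
    io.StringIO(_SUBGROUP_CSV), index_col="device_id"
)
DEMOGRAPHICS_TABLE: pd.DataFrame = pd.read_csv(
    io.StringIO(_DEMOGRAPHICS_CSV), index_col="variable"
)

#: male / female counts per site (rows: site, cols: sex)
SEX_COUNTS = pd.DataFrame(
    [[27, 10], [12, 26]], index=list(SITES), columns=["male", "female"]
)

#: the five devices with the highest overall macro F1
TOP5_DEVICES: tuple[str, ...] = tuple(
    DEVICE_TABLE["macro_f1"].sort_values(ascending=False).head(5).index
)
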