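"""Method-comparison statistics for hypnogram-derived sleep measures.

Bland-Altman analysis quantifies how a device's sleep measure (sleep
efficiency, sleep latency, REM latency, ...) agrees with the
polysomnography value across sessions: the bias is the mean of the
per-session differences (device minus reference, so positive bias means
the device overestimates), the limits of agreement are bias +/- 1.96 SD of
the differences, and proportional bias is assessed as the Pearson
correlation between the pair means and the differences.

Demographic group comparisons follow the usual two-site reporting: Welch
(default) or pooled two-sample t tests for continuous variables and the
Fisher exact test for 2x2 category counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "BlandAltmanResult",
    "GroupComparison",
    "bland_altman",
    "compare_groups_continuous",
    "compare_groups_binary",
]

ALPHA = 0.05
_LOA_Z = 1.96


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bland-Altman summary with proportional-bias test.

    ``prop_bias_defined`` is False when the correlation cannot be computed
    (fewer than three pairs, or zero spread in the means or differences);
    the correlation fields are then NaN and ``prop_bias_significant`` False.
    """

    n: int
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    prop_bias_r: float
    prop_bias_p: float
    prop_bias_significant: bool
    prop_bias_defined: bool = True


@dataclass(frozen=True)
class GroupComparison:
    statistic: float
    p_value: float
    test_name: Literal["two-sample t", "Fisher exact"]
    significant: bool
    degenerate: bool = False


def bland_altman(
    device_values: Sequence[float], reference_values: Sequence[float]
) -> BlandAltmanResult:
    """Bland-Altman agreement of paired measures (device minus reference)."""
    dev = np.asarray(device_values, dtype=float)
    ref = np.asarray(reference_values, dtype=float)
    if dev.shape != ref.shape or dev.ndim != 1:
        raise ValueError("device and reference value sequences must match in length")
    n = dev.size
    if n < 1:
        raise ValueError("at least one pair is required")

    diffs = dev - ref
    means = (dev + ref) / 2.0
    bias = float(diffs.mean())
    sd_diff = float(diffs.std(ddof=1)) if n > 1 else 0.0

    r = p = math.nan
    defined = n >= 3 and np.std(means) > 0 and np.std(diffs) > 0
    if defined:
        r, p = stats.pearsonr(means, diffs)
        r, p = float(r), float(p)

    return BlandAltmanResult(
        n=n,
        bias=bias,
        sd_diff=sd_diff,
        loa_low=bias - _LOA_Z * sd_diff,
        loa_high=bias + _LOA_Z * sd_diff,
        prop_bias_r=r,
        prop_bias_p=p,
        prop_bias_significant=bool(defined and p < ALPHA),
        prop_bias_defined=bool(defined),
    )


def compare_groups_continuous(
    a: Sequence[float],
    b: Sequence[float],
    variant: Literal["pooled", "welch"] = "welch",
) -> GroupComparison:
    """Two-sided two-sample t test (Welch by default)."""
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least two observations")

    if a.std() == 0 and b.std() == 0:
        # no within-group variability: identical means are indistinguishable
        if a.mean() == b.mean():
            return GroupComparison(0.0, 1.0, "two-sample t", False, degenerate=True)
        return GroupComparison(math.inf, 0.0, "two-sample t", True, degenerate=True)

    res = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    stat, p = float(res.statistic), float(res.pvalue)
    return GroupComparison(stat, p, "two-sample t", bool(p < ALPHA))


def compare_groups_binary(table: Sequence[Sequence[int]]) -> GroupComparison:
    """Two-sided Fisher exact test on a 2x2 count table.

    The two-sided p sums the hypergeometric probabilities of all tables
    (with the observed margins) no more probable than the observed one.
    A zero margin makes every statistic degenerate: p = 1, flagged.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError("Fisher exact test requires a 2x2 table")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")

    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return GroupComparison(math.nan, 1.0, "Fisher exact", False, degenerate=True)

    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return GroupComparison(float(odds), float(p), "Fisher exact", bool(p < ALPHA))
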