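"""Summary sleep measures derived from a single hypnogram.

Definitions (all computed in integer seconds on the 1-second grid,
converted to reporting units only at the end):

* TIB   — time in bed, the full recording duration.
* onset — first second carrying any non-WAKE label.
* SOL   — sleep onset latency, seconds before onset.
* TST   — total sleep time, all non-WAKE seconds.
* WASO  — wake after sleep onset, WAKE seconds at or after onset.
* SE    — sleep efficiency, 100 * TST / TIB.
* REM latency — minutes from sleep onset (optionally record start) to the
  first REM second; absent when the night contains no REM (or no sleep).

These satisfy the partition identity TIB = SOL + TST + WASO exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .hypnogram import REM, WAKE, Hypnogram, expand_to_seconds

__all__ = ["SleepMeasures", "derive_measures"]

_S_PER_H = 3600.0


@dataclass(frozen=True)
class SleepMeasures:
    """The six reported measures (hours / percent / minutes).

    ``rem_latency_min`` is NaN with ``rem_present=False`` when no REM sleep
    occurred; ``onset_present=False`` marks an all-wake night, in which case
    SOL equals TIB and TST = WASO = SE = 0.
    """

    tib_h: float
    tst_h: float
    sol_h: float
    waso_h: float
    se_pct: float
    rem_latency_min: float
    onset_present: bool = True
    rem_present: bool = True


def derive_measures(
    h: Hypnogram,
    rem_latency_reference: Literal["onset", "start"] = "onset",
) -> SleepMeasures:
    """Derive :class:`SleepMeasures` from one hypnogram.

    Parameters
    ----------
    h:
        The hypnogram (any source, any epoch duration).
    rem_latency_reference:
        Whether REM latency counts from sleep onset (the sleep-medicine
        convention, default) or from the start of the recording.
    """
    if rem_latency_reference not in ("onset", "start"):
        raise ValueError("rem_latency_reference must be 'onset' or 'start'")

    sec = expand_to_seconds(h)
    tib_s = int(sec.size)
    sleep = sec != WAKE

    if not sleep.any():
        return SleepMeasures(
            tib_h=tib_s / _S_PER_H,
            tst_h=0.0,
            sol_h=tib_s / _S_PER_H,
            waso_h=0.0,
            se_pct=0.0,
            rem_latency_min=math.nan,
            onset_present=False,
            rem_present=False,
        )

    onset_s = int(np.argmax(sleep))
    tst_s = int(sleep.sum())
    waso_s = tib_s - onset_s - tst_s

    rem_idx = np.flatnonzero(sec == REM)
    if rem_idx.size:
        origin = onset_s if rem_latency_reference == "onset" else 0
        rem_latency_min = (int(rem_idx[0]) - origin) / 60.0
        rem_present = True
    else:
        rem_latency_min = math.nan
        rem_present = False

    return SleepMeasures(
        tib_h=tib_s / _S_PER_H,
        tst_h=tst_s / _S_PER_H,
        sol_h=onset_s / _S_PER_H,
        waso_h=waso_s / _S_PER_H,
        se_pct=100.0 * tst_s / tib_s,
        rem_latency_min=rem_latency_min,
        onset_present=True,
        rem_present=rem_present,
    )
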