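"""Cohort-level aggregation of per-session agreement results.

Builds the reporting surfaces of a multi-device validation study: one row
per device (epoch-by-epoch summary plus one-vs-rest stage metrics, with the
number of distinct participants), per-site averages of the device macro F1,
device x subgroup macro-F1 matrices (AHI / sleep-efficiency / BMI / sex
splits), the per-stage winner margins, top-k stage averages, and the
per-device min-max normalised matrix used for rank heatmaps.

Two pooling modes are supported everywhere a device-level metric is formed:

* ``pooled`` (default) — sum the per-second confusion counts over all of a
  device's sessions and compute metrics on the summed matrix; this weights
  every compared second equally and is how headline tables are built.
* ``per_participant`` — compute metrics per participant and average them,
  weighting every participant equally.

The two modes genuinely differ (metrics are not linear in the counts), so
the mode is an explicit argument, never a hidden default switch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .agreement import ConfusionMatrix4, stage_metrics, summary_metrics
from .hypnogram import N_STAGES, STAGE_NAMES
from .measures import SleepMeasures

__all__ = [
    "Demographics",
    "SessionResult",
    "SubgroupSpec",
    "StageMargin",
    "DEFAULT_SUBGROUP_SPECS",
    "round_half_up",
    "device_table",
    "site_average_macro_f1",
    "subgroup_table",
    "subgroup_column_means",
    "subgroup_side_differences",
    "stage_margin",
    "top_k_stage_average",
    "rank_heatmap_matrix",
]

logger = logging.getLogger(__name__)

PoolingMode = Literal["pooled", "per_participant"]
DEVICE_CLASSES = ("wearable", "nearable", "airable")


def round_half_up(x: float, decimals: int = 4) -> float:
    """Round with ties away from zero, as printed tables conventionally do."""
    if isinstance(x, float) and (np.isnan(x) or np.isinf(x)):
        return x
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Demographics:
    sex: str
    age: float
    bmi: float
    ahi: float


@dataclass(frozen=True)
class SessionResult:
    """Everything the aggregators need from one (session, device) pair."""

    session_id: str
    participant_id: str
    device_id: str
    device_class: str
    site: str
    confusion: ConfusionMatrix4
    measures_device: SleepMeasures
    measures_reference: SleepMeasures
    demographics: Demographics

    def __post_init__(self) -> None:
        if self.device_class not in DEVICE_CLASSES:
            raise ValueError(
                f"device_class must be one of {DEVICE_CLASSES}, "
                f"got {self.device_class!r}"
            )


@dataclass(frozen=True)
class SubgroupSpec:
    """A binary participant split: threshold on a covariate, or sex."""

    variable: Literal["ahi", "se_pct", "bmi", "sex"]
    threshold: float = float("nan")
    sides: tuple[str, str] = ()

    def __post_init__(self) -> None:
        if not self.sides:
            if self.variable == "sex":
                sides = ("male", "female")
            else:
                t = _fmt_num(self.threshold)
                sides = (f"{self.variable}<={t}", f"{self.variable}>{t}")
            object.__setattr__(self, "sides", sides)

    def side_of(self, demo: Demographics, reference_se_pct: float) -> str:
        if self.variable == "sex":
            return str(demo.sex).lower()
        value = {
            "ahi": demo.ahi,
            "bmi": demo.bmi,
            "se_pct": reference_se_pct,
        }[self.variable]
        return self.sides[0] if value <= self.threshold else self.sides[1]


def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else str(x)


#: the conventional splits: AHI 15 events/h, sleep efficiency 85 %, BMI 25
DEFAULT_SUBGROUP_SPECS = (
    SubgroupSpec("ahi", 15.0),
    SubgroupSpec("se_pct", 85.0),
    SubgroupSpec("bmi", 25.0),
    SubgroupSpec("sex"),
)

_STAGE_COLS = [
    f"{name}_{metric}"
    for name in STAGE_NAMES.values()
    for metric in ("f1", "sensitivity", "specificity")
]


def _device_class_registry(results: Iterable[SessionResult]) -> dict[str, str]:
    registry: dict[str, str] = {}
    for r in results:
        prev = registry.setdefault(r.device_id, r.device_class)
        if prev != r.device_class:
            raise ValueError(
                f"device {r.device_id!r} appears with inconsistent classes "
                f"{prev!r} and {r.device_class!r}"
            )
    return registry


def _metrics_row(cm: ConfusionMatrix4) -> dict[str, float]:
    s = summary_metrics(cm)
    row = {
        "accuracy": s.accuracy,
        "weighted_f1": s.weighted_f1,
        "kappa": s.kappa,
        "macro_f1": s.macro_f1,
    }
    for stage, name in STAGE_NAMES.items():
        m = stage_metrics(cm, stage)
        row[f"{name}_f1"] = m.f1
        row[f"{name}_sensitivity"] = m.sensitivity
        row[f"{name}_specificity"] = m.specificity
    return row


def _device_metrics(
    sessions: Sequence[SessionResult], mode: PoolingMode
) -> dict[str, float]:
    if mode == "pooled":
        total = ConfusionMatrix4(
            np.sum([r.confusion.counts for r in sessions], axis=0)
        )
        return _metrics_row(total)
    if mode == "per_participant":
        per_part: dict[str, list[SessionResult]] = {}
        for r in sessions:
            per_part.setdefault(r.participant_id, []).append(r)
        rows = []
        for part_sessions in per_part.values():
            cm = ConfusionMatrix4(
                np.sum([r.confusion.counts for r in part_sessions], axis=0)
            )
            rows.append(_metrics_row(cm))
        frame = pd.DataFrame(rows)
        return frame.mean().to_dict()  # NaN-aware participant average
    raise ValueError("mode must be 'pooled' or 'per_participant'")


def device_table(
    results: Sequence[SessionResult],
    mode: PoolingMode = "pooled",
    site: str | None = None,
) -> pd.DataFrame:
    """One row per device: n participants, summary and stage metrics.

    ``site`` restricts to one recruitment site (device rows then reflect
    that site's sessions only, as per-site table columns do).
    """
    registry = _device_class_registry(results)
    if site is not None:
        results = [r for r in results if r.site == site]
    by_device: dict[str, list[SessionResult]] = {}
    for r in results:
        by_device.setdefault(r.device_id, []).append(r)

    rows = []
    for device_id, sessions in sorted(by_device.items()):
        row: dict[str, object] = {
            "device_id": device_id,
            "device_class": registry[device_id],
            "n": len({r.participant_id for r in sessions}),
        }
        row.update(_device_metrics(sessions, mode))
        rows.append(row)
    table = pd.DataFrame(rows)
    return table.set_index("device_id") if len(table) else table


def site_average_macro_f1(macro_f1_values: Sequence[float]) -> float:
    """Unweighted mean of per-device macro F1, reporting-rounded (4 dp).

    The input is one site's column of the device table (or any published
    per-device values); devices are weighted equally regardless of n.
    """
    values = np.asarray(macro_f1_values, dtype=float)
    if values.size == 0:
        raise ValueError("need at least one device macro F1")
    return round_half_up(float(values.mean()), 4)


def subgroup_table(
    results: Sequence[SessionResult],
    specs: Sequence[SubgroupSpec] = DEFAULT_SUBGROUP_SPECS,
    mode: PoolingMode = "pooled",
) -> pd.DataFrame:
    """Device x subgroup-side macro-F1 matrix.

    Subgroup membership is per participant; the sleep-efficiency split uses
    the polysomnography-derived sleep efficiency.  Cells with no sessions
    are NaN (logged) and are skipped by the column means.
    """
    devices = sorted({r.device_id for r in results})
    _device_class_registry(results)
    columns: list[str] = [side for spec in specs for side in spec.sides]
    table = pd.DataFrame(index=pd.Index(devices, name="device_id"),
                         columns=columns, dtype=float)

    for spec in specs:
        for side in spec.sides:
            for device_id in devices:
                members = [
                    r
                    for r in results
                    if r.device_id == device_id
                    and spec.side_of(r.demographics, r.measures_reference.se_pct)
                    == side
                ]
                if not members:
                    logger.info(
                        "subgroup cell empty: device=%s side=%s", device_id, side
                    )
                    continue
                table.loc[device_id, side] = _device_metrics(members, mode)[
                    "macro_f1"
                ]
    return table


def subgroup_column_means(table: pd.DataFrame, decimals: int = 4) -> pd.Series:
    """Unweighted per-column device means of a subgroup matrix, rounded.

    NaN cells (empty subgroups) are excluded from their column's mean.
    """
    return table.mean(axis=0, skipna=True).map(lambda v: round_half_up(v, decimals))


def subgroup_side_differences(
    table: pd.DataFrame, specs: Sequence[SubgroupSpec] = DEFAULT_SUBGROUP_SPECS
) -> pd.DataFrame:
    """Per-device |left - right| for each subgroup variable.

    The device with the largest difference for a variable is the one whose
    performance varies most across that split.
    """
    out = pd.DataFrame(index=table.index)
    for spec in specs:
        left, right = spec.sides
        out[spec.variable] = (table[left] - table[right]).abs()
    return out


@dataclass(frozen=True)
class StageMargin:
    top_device: str
    runner_up: str
    margin: float
    tie: bool = False
    tied_devices: tuple[str, ...] = field(default_factory=tuple)


def stage_margin(stage_f1: Mapping[str, float] | pd.Series) -> StageMargin:
    """Top device, runner-up and their F1 margin for one stage (4 dp)."""
    s = pd.Series(stage_f1, dtype=float).dropna()
    if s.size < 2:
        raise ValueError("need at least two devices to compute a margin")
    order = s.sort_values(ascending=False)
    top, runner = order.index[0], order.index[1]
    margin = round_half_up(float(order.iloc[0] - order.iloc[1]), 4)
    tie = margin == 0.0
    tied = tuple(order.index[order.values == order.iloc[0]]) if tie else ()
    return StageMargin(str(top), str(runner), margin, tie, tied)


def top_k_stage_average(
    stage_f1: Mapping[str, float] | pd.Series,
    device_subset: Sequence[str],
    decimals: int = 3,
) -> float:
    """Unweighted mean stage F1 over a named device subset (3 dp default)."""
    s = pd.Series(stage_f1, dtype=float)
    missing = [d for d in device_subset if d not in s.index]
    if missing:
        raise KeyError(f"unknown devices in subset: {missing}")
    if len(device_subset) == 0:
        raise ValueError("device subset must not be empty")
    return round_half_up(float(s.loc[list(device_subset)].mean()), decimals)


def rank_heatmap_matrix(metric_table: pd.DataFrame) -> pd.DataFrame:
    """Min-max normalise each device row: best measure 1, worst 0.

    Rows with zero range (a device identical on every measure) cannot be
    normalised; they are returned as all-NaN and logged.
    """
    if metric_table.shape[1] < 2:
        raise ValueError("need at least two measures per device")
    values = metric_table.astype(float)
    lo = values.min(axis=1)
    hi = values.max(axis=1)
    rng = hi - lo
    constant = rng == 0
    for device in values.index[constant]:
        logger.warning("rank heatmap: constant row flagged for %s", device)
    safe = rng.replace(0, np.nan)
    return values.sub(lo, axis=0).div(safe, axis=0)
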