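"""Epoch-by-epoch agreement statistics on the 1-second grid.

Everything derives from the 4x4 confusion matrix of per-second counts,
with reference (polysomnography) stages on the rows and device stages on
the columns: overall accuracy, per-stage one-vs-rest F1 / sensitivity /
specificity, macro and support-weighted F1, and unweighted Cohen's kappa.
Macro F1 and kappa are the headline summaries because the stage
distribution is heavily imbalanced (most of a night is light sleep).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .hypnogram import N_STAGES, STAGE_NAMES, AlignedPair

__all__ = [
    "ConfusionMatrix4",
    "NormalizedConfusion",
    "StageMetrics",
    "AgreementSummary",
    "confusion_matrix",
    "normalize_confusion",
    "stage_metrics",
    "summary_metrics",
    "kappa_band",
]


@dataclass(frozen=True)
class ConfusionMatrix4:
    """4x4 per-second count matrix; rows = reference stage, cols = device."""

    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (N_STAGES, N_STAGES):
            raise ValueError("confusion matrix must be 4x4")
        if (counts < 0).any():
            raise ValueError("confusion matrix entries must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total_seconds(self) -> int:
        return int(self.counts.sum())

    @property
    def row_support(self) -> np.ndarray:
        """Seconds of each reference stage."""
        return self.counts.sum(axis=1)

    @property
    def col_support(self) -> np.ndarray:
        """Seconds of each device-reported stage."""
        return self.counts.sum(axis=0)

    def __add__(self, other: "ConfusionMatrix4") -> "ConfusionMatrix4":
        return ConfusionMatrix4(self.counts + other.counts)


@dataclass(frozen=True)
class NormalizedConfusion:
    """Row-stochastic confusion proportions; zero-support rows flagged."""

    proportions: np.ndarray = field(repr=False)
    zero_support_rows: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class StageMetrics:
    """One-vs-rest metrics for a single stage.

    ``sensitivity`` is NaN with ``sensitivity_defined=False`` when the
    reference contains no second of the stage.  ``f1`` is 0 with
    ``f1_degenerate=True`` when the stage appears in neither stream's
    positive set (both precision and sensitivity vanish).
    """

    stage: int
    f1: float
    sensitivity: float
    specificity: float
    support: int
    sensitivity_defined: bool = True
    specificity_defined: bool = True
    f1_degenerate: bool = False


@dataclass(frozen=True)
class AgreementSummary:
    """Multiclass summary: accuracy, macro/weighted F1 and Cohen's kappa."""

    accuracy: float
    macro_f1: float
    weighted_f1: float
    kappa: float
    kappa_defined: bool = True


def confusion_matrix(pair: AlignedPair) -> ConfusionMatrix4:
    """Tally the 4x4 per-second confusion counts of an aligned pair."""
    idx = pair.reference_seconds.astype(np.int64) * N_STAGES + pair.device_seconds
    counts = np.bincount(idx, minlength=N_STAGES * N_STAGES)
    return ConfusionMatrix4(counts.reshape(N_STAGES, N_STAGES))


def normalize_confusion(cm: ConfusionMatrix4) -> NormalizedConfusion:
    """Row-normalize to stage-conditional proportions.

    Rows with zero reference support are left all-zero and flagged rather
    than dividing by zero.
    """
    support = cm.row_support
    zero = support == 0
    denom = np.where(zero, 1, support).astype(float)
    props = cm.counts / denom[:, None]
    props[zero] = 0.0
    return NormalizedConfusion(proportions=props, zero_support_rows=zero)


def stage_metrics(cm: ConfusionMatrix4, stage: int) -> StageMetrics:
    """One-vs-rest F1, sensitivity and specificity for ``stage``."""
    if stage not in STAGE_NAMES:
        raise ValueError(f"stage must be one of {sorted(STAGE_NAMES)}")
    c = cm.counts
    tp = int(c[stage, stage])
    fn = int(c[stage].sum() - tp)
    fp = int(c[:, stage].sum() - tp)
    tn = int(c.sum() - tp - fn - fp)

    sens_defined = (tp + fn) > 0
    sensitivity = tp / (tp + fn) if sens_defined else math.nan
    spec_defined = (tn + fp) > 0
    specificity = tn / (tn + fp) if spec_defined else math.nan

    degenerate = (2 * tp + fp + fn) == 0
    f1 = 0.0 if degenerate else 2 * tp / (2 * tp + fp + fn)

    return StageMetrics(
        stage=stage,
        f1=f1,
        sensitivity=sensitivity,
        specificity=specificity,
        support=tp + fn,
        sensitivity_defined=sens_defined,
        specificity_defined=spec_defined,
        f1_degenerate=degenerate,
    )


def summary_metrics(cm: ConfusionMatrix4) -> AgreementSummary:
    """Accuracy, macro F1, support-weighted F1 and unweighted Cohen kappa.

    kappa = (p_o - p_e) / (1 - p_e) with p_e from the row/column marginal
    products.  When both raters are constant and identical, p_e = 1 and
    kappa is undefined: returned as NaN with ``kappa_defined=False``.
    """
    n = cm.total_seconds
    if n == 0:
        raise ValueError("empty confusion matrix")
    c = cm.counts
    accuracy = float(np.trace(c)) / n

    f1s = np.array([stage_metrics(cm, s).f1 for s in range(N_STAGES)])
    support = cm.row_support
    macro_f1 = float(f1s.mean())
    weighted_f1 = float((f1s * support).sum() / n)

    p_o = accuracy
    p_e = float((cm.row_support * cm.col_support).sum()) / (n * n)
    if p_e >= 1.0 - 1e-15:
        return AgreementSummary(accuracy, macro_f1, weighted_f1, math.nan, False)
    kappa = (p_o - p_e) / (1.0 - p_e)
    return AgreementSummary(accuracy, macro_f1, weighted_f1, kappa, True)


#: interrater-agreement bands for Cohen's kappa
_KAPPA_BANDS = (
    (0.2, "slight"),
    (0.4, "fair"),
    (0.6, "moderate"),
    (0.8, "substantial"),
    (1.0, "almost perfect"),
)


def kappa_band(kappa: float) -> str:
    """Verbal agreement category of a kappa value (poor below 0)."""
    if not -1.0 <= kappa <= 1.0:
        raise ValueError("kappa must lie in [-1, 1]")
    if kappa <= 0.0:
        return "poor"
    for upper, name in _KAPPA_BANDS:
        if kappa <= upper:
            return name
    return "almost perfect"  # pragma: no cover
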