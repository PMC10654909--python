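"""Hypnogram representation, label standardization and temporal alignment.

A hypnogram is a timed sequence of sleep-stage labels at a fixed epoch
duration (30 s for laboratory polysomnography, device-dependent for consumer
sleep trackers).  Stages use a fixed four-class coding:

    0 = WAKE, 1 = LIGHT, 2 = DEEP, 3 = REM

Device exports use vendor-specific wording ("core sleep" for light sleep on
some smartwatches); a :class:`StageVocabulary` maps raw strings onto the
canonical codes and rejects anything it does not know.

For epoch-by-epoch comparison the two label streams are resegmented onto a
common 1-second grid: comparing on the native 30-second grids is biased
whenever the two scorers' epoch boundaries are out of phase, so every stream
is expanded to per-second labels and compared second by second.  Device
streams are then aligned to the reference window: device seconds recorded
before the reference started are discarded, a late device start is padded
with WAKE, and the endpoint is clipped (or WAKE-padded) to the reference end
so every aligned pair spans exactly the reference's time in bed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "WAKE",
    "LIGHT",
    "DEEP",
    "REM",
    "N_STAGES",
    "STAGE_NAMES",
    "StageVocabulary",
    "Hypnogram",
    "AlignedPair",
    "UnmappedLabelError",
    "AlignmentError",
    "map_stage_labels",
    "expand_to_seconds",
    "align_to_reference",
]

WAKE: int = 0
LIGHT: int = 1
DEEP: int = 2
REM: int = 3
N_STAGES: int = 4

#: canonical lower-case name of each stage code
STAGE_NAMES: dict[int, str] = {WAKE: "wake", LIGHT: "light", DEEP: "deep", REM: "rem"}

_VALID_CODES = frozenset(range(N_STAGES))


class UnmappedLabelError(KeyError):
    """A raw device label is absent from the device's stage vocabulary."""


class AlignmentError(ValueError):
    """Device and reference recordings share no overlap; session unusable."""


@dataclass(frozen=True)
class StageVocabulary:
    """Total map from one device's raw stage strings to canonical codes.

    Parameters
    ----------
    device_id:
        Identifier of the device this vocabulary belongs to.
    mapping:
        Raw label string -> stage code in {0, 1, 2, 3}.  Lookup is exact
        (no normalisation is applied); an unknown label raises
        :class:`UnmappedLabelError` rather than being silently coerced.
    """

    device_id: str
    mapping: Mapping[str, int]

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.mapping.items() if v not in _VALID_CODES}
        if bad:
            raise ValueError(
                f"vocabulary for {self.device_id!r} maps to invalid codes: {bad}"
            )

    def map(self, raw: str) -> int:
        try:
            return self.mapping[raw]
        except KeyError:
            raise UnmappedLabelError(
                f"label {raw!r} is not in the vocabulary of device "
                f"{self.device_id!r}"
            ) from None

    def inverse(self) -> dict[int, str]:
        """First raw string listed for each code (for writing exports)."""
        inv: dict[int, str] = {}
        for raw, code in self.mapping.items():
            inv.setdefault(code, raw)
        return inv


#: canonical vocabulary used for the polysomnography reference
CANONICAL_VOCABULARY = StageVocabulary(
    "psg", {"wake": WAKE, "light": LIGHT, "deep": DEEP, "rem": REM}
)


@dataclass(frozen=True)
class Hypnogram:
    """One source's staged night: labels at a fixed epoch duration.

    ``start_time`` is in whole seconds on the session clock (seconds since
    the session origin; the reference usually starts at 0).  Sub-second
    start times are floored, since 1 s is the finest comparison grid.
    """

    source_id: str
    start_time: int
    epoch_duration: int
    labels: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int8)
        if labels.ndim != 1 or labels.size < 1:
            raise ValueError("hypnogram must contain at least one epoch")
        if not np.isin(labels, list(_VALID_CODES)).all():
            raise ValueError("stage codes must be in {0, 1, 2, 3}")
        epoch = int(self.epoch_duration)
        if epoch <= 0 or epoch != self.epoch_duration:
            raise ValueError("epoch_duration must be a positive whole second count")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "epoch_duration", epoch)
        object.__setattr__(self, "start_time", int(math.floor(self.start_time)))

    @property
    def n_epochs(self) -> int:
        return int(self.labels.size)

    @property
    def duration_s(self) -> int:
        return self.n_epochs * self.epoch_duration

    @property
    def end_time(self) -> int:
        return self.start_time + self.duration_s


@dataclass(frozen=True)
class AlignedPair:
    """Reference and device per-second label streams of identical length.

    ``n_seconds`` always equals the reference duration in seconds;
    the bookkeeping counters record how the device stream was fitted to
    that window (head seconds discarded because the device started early,
    head/tail seconds padded with WAKE because it started late or stopped
    early).
    """

    reference_seconds: np.ndarray = field(repr=False)
    device_seconds: np.ndarray = field(repr=False)
    n_seconds: int
    padded_head_seconds: int = 0
    discarded_head_seconds: int = 0
    padded_tail_seconds: int = 0

    def __post_init__(self) -> None:
        ref = np.asarray(self.reference_seconds, dtype=np.int8)
        dev = np.asarray(self.device_seconds, dtype=np.int8)
        if ref.shape != dev.shape or ref.ndim != 1:
            raise ValueError("reference and device streams must be 1-D and equal length")
        if ref.size != self.n_seconds:
            raise ValueError("n_seconds does not match the stream length")
        object.__setattr__(self, "reference_seconds", ref)
        object.__setattr__(self, "device_seconds", dev)


def map_stage_labels(
    raw_labels: Sequence[str],
    vocab: StageVocabulary,
    start_time: int,
    epoch_duration: int,
    source_id: str | None = None,
) -> Hypnogram:
    """Standardize raw device labels into a canonical-coded hypnogram.

    Raises
    ------
    ValueError
        If ``raw_labels`` is empty.
    UnmappedLabelError
        Naming the offending label and device, if any label is unknown.
    """
    if len(raw_labels) == 0:
        raise ValueError(
            f"empty label sequence for device {vocab.device_id!r}: a hypnogram "
            "needs at least one epoch"
        )
    codes = np.fromiter((vocab.map(raw) for raw in raw_labels), dtype=np.int8,
                        count=len(raw_labels))
    return Hypnogram(
        source_id=source_id or vocab.device_id,
        start_time=start_time,
        epoch_duration=epoch_duration,
        labels=codes,
    )


def expand_to_seconds(h: Hypnogram) -> np.ndarray:
    """Resegment a hypnogram to the 1-second grid (each label repeated)."""
    return np.repeat(h.labels, h.epoch_duration)


def align_to_reference(device: Hypnogram, psg: Hypnogram) -> AlignedPair:
    """Fit a device stream to the reference window on the 1-second grid.

    Device seconds recorded before the reference start are discarded; if the
    device started late the gap is scored WAKE; the device stream is
    truncated at the reference end, and a device that stopped early is
    WAKE-padded to the end (with a warning, since that tail was never
    observed by the device).

    Raises
    ------
    AlignmentError
        If the device and reference windows do not overlap at all.
    """
    ref_sec = expand_to_seconds(psg)
    n = ref_sec.size

    overlap_start = max(device.start_time, psg.start_time)
    overlap_end = min(device.end_time, psg.end_time)
    if overlap_end <= overlap_start:
        raise AlignmentError(
            f"device {device.source_id!r} window [{device.start_time}, "
            f"{device.end_time}) has no overlap with reference "
            f"[{psg.start_time}, {psg.end_time})"
        )

    dev_sec = expand_to_seconds(device)
    discarded_head = max(0, psg.start_time - device.start_time)
    padded_head = max(0, device.start_time - psg.start_time)
    padded_tail = max(0, psg.end_time - device.end_time)

    out = np.full(n, WAKE, dtype=np.int8)
    # slice of the device stream that falls inside the reference window
    dev_slice = dev_sec[discarded_head : discarded_head + (overlap_end - overlap_start)]
    pos = overlap_start - psg.start_time
    out[pos : pos + dev_slice.size] = dev_slice

    if padded_tail > 0:
        warnings.warn(
            f"device {device.source_id!r} ended {padded_tail} s before the "
            "reference; tail scored WAKE",
            stacklevel=2,
        )

    return AlignedPair(
        reference_seconds=ref_sec,
        device_seconds=out,
        n_seconds=n,
        padded_head_seconds=padded_head,
        discarded_head_seconds=discarded_head,
        padded_tail_seconds=padded_tail,
    )
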