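"""CSV / JSON ingestion boundary.

Vendor export formats (app JSON dumps, health-platform XML, EDF) are out of
scope: a hypnogram enters the pipeline as a documented CSV with one row per
epoch — ``onset_s`` (integer seconds from the session origin),
``duration_s`` and a raw ``stage`` string — one file per source per
session.  Stage vocabularies are JSON objects mapping raw strings to the
canonical codes.  The session manifest is a CSV with one row per
(session, source) and the participant demographics.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .hypnogram import Hypnogram, StageVocabulary, map_stage_labels

__all__ = [
    "MANIFEST_COLUMNS",
    "read_vocabulary",
    "write_vocabulary",
    "read_hypnogram_csv",
    "write_hypnogram_csv",
    "read_manifest",
    "write_manifest",
]

MANIFEST_COLUMNS = (
    "session_id",
    "participant_id",
    "site",
    "device_id",
    "hypnogram_path",
    "role",
    "device_class",
    "sex",
    "age",
    "bmi",
    "ahi",
)

ROLES = ("reference", "device")


def read_vocabulary(path: str | Path, device_id: str | None = None) -> StageVocabulary:
    """Load a raw-label -> stage-code vocabulary from a JSON file."""
    path = Path(path)
    with open(path) as fh:
        mapping = json.load(fh)
    if not isinstance(mapping, dict):
        raise ValueError(f"vocabulary file {path} must contain a JSON object")
    return StageVocabulary(device_id or path.stem, {str(k): int(v) for k, v in mapping.items()})


def write_vocabulary(vocab: StageVocabulary, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(dict(vocab.mapping), fh, indent=1)
        fh.write("\n")


def read_hypnogram_csv(
    path: str | Path, vocab: StageVocabulary, source_id: str | None = None
) -> Hypnogram:
    """Read one source's hypnogram CSV and standardize its labels.

    The file must describe a contiguous, fixed-epoch recording: rows sorted
    by onset, all ``duration_s`` equal, each onset following the previous
    epoch's end.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    required = {"onset_s", "duration_s", "stage"}
    if not required.issubset(frame.columns):
        raise ValueError(f"hypnogram file {path} lacks columns {sorted(required - set(frame.columns))}")
    if len(frame) == 0:
        raise ValueError(f"hypnogram file {path} is empty")

    durations = frame["duration_s"].to_numpy()
    if len(np.unique(durations)) != 1:
        raise ValueError(f"hypnogram file {path} has variable epoch durations")
    epoch = int(durations[0])
    onsets = frame["onset_s"].to_numpy(dtype=np.int64)
    if not (np.diff(onsets) == epoch).all():
        raise ValueError(f"hypnogram file {path} is not contiguous on its epoch grid")

    return map_stage_labels(
        frame["stage"].astype(str).tolist(),
        vocab,
        start_time=int(onsets[0]),
        epoch_duration=epoch,
        source_id=source_id,
    )


def write_hypnogram_csv(
    h: Hypnogram, path: str | Path, vocab: StageVocabulary | None = None
) -> None:
    """Write a hypnogram as the epoch-per-row CSV, using ``vocab`` for the
    raw stage strings (canonical names when omitted)."""
    from .hypnogram import CANONICAL_VOCABULARY

    inverse = (vocab or CANONICAL_VOCABULARY).inverse()
    onsets = h.start_time + np.arange(h.n_epochs, dtype=np.int64) * h.epoch_duration
    frame = pd.DataFrame(
        {
            "onset_s": onsets,
            "duration_s": h.epoch_duration,
            "stage": [inverse[int(code)] for code in h.labels],
        }
    )
    frame.to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read the session manifest; validates columns and roles."""
    frame = pd.read_csv(path, dtype={"session_id": str, "participant_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"manifest {path} lacks columns {missing}")
    bad_roles = set(frame["role"].unique()) - set(ROLES)
    if bad_roles:
        raise ValueError(f"manifest {path} has invalid roles {sorted(bad_roles)}")
    return frame


def write_manifest(frame: pd.DataFrame, path: str | Path) -> None:
    frame.loc[:, list(MANIFEST_COLUMNS)].to_csv(path, index=False)
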