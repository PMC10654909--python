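"""Synthetic two-site cohort generator.

No raw recordings exist for the validation study this package reproduces,
so every pipeline stage is exercised on simulated data with a controlled,
recoverable error structure:

* **Reference nights** are first-order Markov chains over the four stages
  at the 30-second polysomnography epoch.  The default chain is a "sticky
  resampling" chain, ``P = (1 - r) I + 1 pi^T r``: each epoch the stage
  persists with probability ``1 - r`` and is otherwise redrawn from the
  stationary distribution ``pi``.  The defaults were calibrated offline
  (``scripts/calibrate_architecture.py``) so that a cohort with time in
  bed ~ N(7.24 h, 0.92 h) reproduces the study-level sleep measures:
  mean sleep latency 0.27 h, WASO 1.15 h, total sleep time 5.8 h, sleep
  efficiency ~81 %, and a deep-stage share of ~10.8 % of epochs.
* **Device readings** apply a stage-conditional emission matrix to the
  reference stage at each device epoch's midpoint, plus a start-time
  offset, an independent epoch grid, and session dropout.  The emission
  matrix is the generative twin of the normalized confusion matrix the
  pipeline estimates, which is what makes parameter recovery testable.
* **Demographics** follow the two recruitment sites' published statistics
  (participant counts, sex ratios, age / BMI / AHI moments, per-site time
  in bed).

Default device error models are illustrative archetypes, not fitted
values: wearables mainly misread wake as light, nearables misread REM as
light and are insensitive to deep sleep, airables confuse light and deep
(one of them reporting the majority of the night as deep).

Randomness is split per (participant, device) with ``SeedSequence`` spawn
keys, so adding a device to the roster never perturbs existing sessions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .hypnogram import (
    CANONICAL_VOCABULARY,
    N_STAGES,
    WAKE,
    Hypnogram,
    StageVocabulary,
    expand_to_seconds,
)
from .io import MANIFEST_COLUMNS, write_hypnogram_csv, write_manifest, write_vocabulary

__all__ = [
    "SleepArchitectureParams",
    "DeviceErrorModel",
    "DeviceSpec",
    "SiteConfig",
    "CohortConfig",
    "ConfigError",
    "SimulatedCohort",
    "DEFAULT_STATIONARY",
    "sticky_resampling_matrix",
    "default_architecture",
    "wearable_error_model",
    "nearable_error_model",
    "airable_error_model",
    "deep_biased_error_model",
    "identity_error_model",
    "default_roster",
    "default_cohort_config",
    "cohort_config_from_json",
    "simulate_psg",
    "simulate_device",
    "simulate_cohort",
]

_S_PER_H = 3600.0

#: calibrated stationary distribution over (WAKE, LIGHT, DEEP, REM)
DEFAULT_STATIONARY: tuple[float, float, float, float] = (
    0.169737,
    0.554263,
    0.108,
    0.168,
)
#: calibrated mean sleep-onset latency, in 30-s epochs (0.27 h)
_SOL_EPOCHS = 32.4


class ConfigError(ValueError):
    """A cohort configuration failed validation."""


def _check_row_stochastic(matrix: np.ndarray, what: str) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.shape != (N_STAGES, N_STAGES):
        raise ValueError(f"{what} must be 4x4")
    if (m < 0).any():
        raise ValueError(f"{what} must be non-negative")
    if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError(f"{what} rows must sum to 1")
    return m


def sticky_resampling_matrix(
    stationary: Sequence[float], mean_wake_dwell_epochs: float
) -> np.ndarray:
    """Transition matrix ``(1 - r) I + 1 pi^T r`` with exact stationary pi.

    ``r`` is set so the mean dwell time in WAKE (hence the mean sleep-onset
    latency, since every night starts awake) equals the requested epoch
    count: a stay in state ``i`` ends with probability ``r (1 - pi_i)``.
    """
    pi = np.asarray(stationary, dtype=float)
    if pi.shape != (N_STAGES,) or (pi < 0).any() or not np.isclose(pi.sum(), 1.0):
        raise ValueError("stationary distribution must be a length-4 simplex point")
    r = 1.0 / (mean_wake_dwell_epochs * (1.0 - pi[WAKE]))
    return (1.0 - r) * np.eye(N_STAGES) + r * np.ones((N_STAGES, 1)) * pi[None, :]


@dataclass(frozen=True)
class SleepArchitectureParams:
    """Generative description of a reference (polysomnography) night."""

    epoch_duration: int = 30
    tib_mean_h: float = 7.24
    tib_sd_h: float = 0.92
    transition_matrix: np.ndarray = field(
        default_factory=lambda: sticky_resampling_matrix(
            DEFAULT_STATIONARY, _SOL_EPOCHS
        ),
        repr=False,
    )
    initial_stage: int = WAKE
    target_sol_mean_h: float = 0.27
    target_waso_mean_h: float = 1.15

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "transition_matrix",
            _check_row_stochastic(self.transition_matrix, "transition matrix"),
        )
        if self.epoch_duration <= 0:
            raise ValueError("epoch_duration must be positive")
        if self.tib_mean_h <= 0 or self.tib_sd_h < 0:
            raise ValueError("time-in-bed distribution parameters invalid")
        if self.initial_stage not in range(N_STAGES):
            raise ValueError("initial_stage must be a stage code")


def default_architecture(
    tib_mean_h: float = 7.24, tib_sd_h: float = 0.92, epoch_duration: int = 30
) -> SleepArchitectureParams:
    """Calibrated defaults, optionally with a site-specific time in bed."""
    return SleepArchitectureParams(
        epoch_duration=epoch_duration, tib_mean_h=tib_mean_h, tib_sd_h=tib_sd_h
    )


@dataclass(frozen=True)
class DeviceErrorModel:
    """Stage-conditional measurement error of one device.

    ``emission_matrix[true, reported]`` is the probability the device
    reports ``reported`` during an epoch whose true (reference) stage is
    ``true``; errors are independent across epochs given the truth.
    ``start_offset_s`` shifts the device start relative to the reference
    (negative = device starts early); the device may live on its own epoch
    grid; ``dropout_prob`` is the probability the whole session is lost
    (battery, account or handling failures).
    """

    emission_matrix: np.ndarray = field(repr=False)
    start_offset_s: int = 0
    epoch_duration: int = 30
    dropout_prob: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "emission_matrix",
            _check_row_stochastic(self.emission_matrix, "emission matrix"),
        )
        if self.epoch_duration <= 0:
            raise ValueError("epoch_duration must be positive")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ValueError("dropout_prob must lie in [0, 1]")


def identity_error_model(**kwargs) -> DeviceErrorModel:
    """A perfect device (useful as a pipeline null)."""
    return DeviceErrorModel(emission_matrix=np.eye(N_STAGES), **kwargs)


def wearable_error_model(**kwargs) -> DeviceErrorModel:
    """Archetype: misreads wake as light (motionless wakefulness)."""
    m = np.array(
        [
            [0.45, 0.48, 0.03, 0.04],
            [0.06, 0.80, 0.08, 0.06],
            [0.02, 0.18, 0.78, 0.02],
            [0.04, 0.16, 0.02, 0.78],
        ]
    )
    return DeviceErrorModel(emission_matrix=m, **kwargs)


def nearable_error_model(**kwargs) -> DeviceErrorModel:
    """Archetype: misreads REM as light, weak deep-stage sensitivity."""
    m = np.array(
        [
            [0.55, 0.38, 0.02, 0.05],
            [0.07, 0.80, 0.05, 0.08],
            [0.03, 0.45, 0.50, 0.02],
            [0.05, 0.40, 0.02, 0.53],
        ]
    )
    return DeviceErrorModel(emission_matrix=m, **kwargs)


def airable_error_model(**kwargs) -> DeviceErrorModel:
    """Archetype: confuses the light and deep stages."""
    m = np.array(
        [
            [0.60, 0.28, 0.08, 0.04],
            [0.06, 0.62, 0.26, 0.06],
            [0.02, 0.30, 0.66, 0.02],
            [0.05, 0.15, 0.05, 0.75],
        ]
    )
    return DeviceErrorModel(emission_matrix=m, **kwargs)


def deep_biased_error_model(**kwargs) -> DeviceErrorModel:
    """Archetype: reports the majority of the night as deep sleep."""
    m = np.array(
        [
            [0.25, 0.12, 0.55, 0.08],
            [0.05, 0.25, 0.62, 0.08],
            [0.02, 0.18, 0.78, 0.02],
            [0.05, 0.25, 0.55, 0.15],
        ]
    )
    return DeviceErrorModel(emission_matrix=m, **kwargs)


#: vocabulary with smartwatch-style alternative wording
APPLE_STYLE_VOCABULARY_MAPPING: Mapping[str, int] = {
    "awake": 0,
    "core sleep": 1,
    "deep sleep": 2,
    "rem sleep": 3,
}


@dataclass(frozen=True)
class DeviceSpec:
    """Roster entry: a device, its class, error model and group membership."""

    device_id: str
    device_class: str
    error_model: DeviceErrorModel
    groups: tuple[str, ...] = ("A", "B")
    vocabulary_mapping: Mapping[str, int] = field(
        default_factory=lambda: dict(CANONICAL_VOCABULARY.mapping)
    )

    def vocabulary(self) -> StageVocabulary:
        return StageVocabulary(self.device_id, dict(self.vocabulary_mapping))


@dataclass(frozen=True)
class SiteConfig:
    site_id: str
    n_participants: int
    male_prop: float
    age_mean: float
    age_sd: float
    bmi_mean: float
    bmi_sd: float
    ahi_mean: float
    ahi_sd: float
    tib_mean_h: float
    tib_sd_h: float

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigError(
                f"site {self.site_id!r}: n_participants must be >= 1"
            )
        if not 0.0 <= self.male_prop <= 1.0:
            raise ConfigError(f"site {self.site_id!r}: male_prop must lie in [0, 1]")


@dataclass(frozen=True)
class CohortConfig:
    sites: tuple[SiteConfig, ...]
    devices: tuple[DeviceSpec, ...]
    conflicts: tuple[tuple[str, str], ...] = ()
    architecture: SleepArchitectureParams = field(
        default_factory=SleepArchitectureParams
    )
    seed: int = 0
    groups: tuple[str, ...] = ("A", "B")

    def __post_init__(self) -> None:
        if not self.sites:
            raise ConfigError("at least one site is required")
        if not self.devices:
            raise ConfigError("at least one device is required")
        ids = [d.device_id for d in self.devices]
        if len(set(ids)) != len(ids):
            raise ConfigError("duplicate device ids in roster")
        roster = {d.device_id: d for d in self.devices}
        for a, b in self.conflicts:
            if a not in roster or b not in roster:
                continue
            shared = set(roster[a].groups) & set(roster[b].groups)
            if shared:
                raise ConfigError(
                    f"conflicting devices {a!r} and {b!r} are both assigned "
                    f"to group(s) {sorted(shared)}"
                )


def default_roster() -> tuple[DeviceSpec, ...]:
    """The 11-device two-group roster mirroring the validation study.

    Group-exclusive devices (the radar nearables; at most two watches per
    wrist pair) appear in one group only and therefore reach roughly half
    the cohort; dropout probabilities are set so realized per-device
    participant counts resemble the study's.  Epoch durations and start
    offsets differ across devices to exercise the 1-second resegmentation
    and alignment paths.
    """
    w, n, a = wearable_error_model, nearable_error_model, airable_error_model
    return (
        DeviceSpec("SleepRoutine", "airable",
                   a(start_offset_s=0, dropout_prob=0.10)),
        DeviceSpec("SleepScore", "airable",
                   a(start_offset_s=300, dropout_prob=0.49)),
        DeviceSpec("Pillow", "airable",
                   deep_biased_error_model(start_offset_s=-15, epoch_duration=15,
                                           dropout_prob=0.01)),
        DeviceSpec("Withings Sleep Tracking Mat", "nearable",
                   n(start_offset_s=-300, epoch_duration=60, dropout_prob=0.0)),
        DeviceSpec("Google Nest Hub 2", "nearable",
                   n(start_offset_s=120, epoch_duration=60, dropout_prob=0.10),
                   groups=("A",)),
        DeviceSpec("Amazon Halo Rise", "nearable",
                   n(start_offset_s=-60, dropout_prob=0.25), groups=("B",)),
        DeviceSpec("Google Pixel Watch", "wearable",
                   w(start_offset_s=60, dropout_prob=0.19), groups=("A",)),
        DeviceSpec("Fitbit Sense 2", "wearable",
                   w(start_offset_s=30, dropout_prob=0.30), groups=("A",)),
        DeviceSpec("Galaxy Watch 5", "wearable",
                   w(start_offset_s=-45, dropout_prob=0.42), groups=("B",)),
        DeviceSpec("Apple Watch 8", "wearable",
                   w(start_offset_s=90, dropout_prob=0.32), groups=("B",),
                   vocabulary_mapping=dict(APPLE_STYLE_VOCABULARY_MAPPING)),
        DeviceSpec("Oura Ring 3", "wearable",
                   w(start_offset_s=-120, epoch_duration=60, dropout_prob=0.29)),
    )


#: devices that share a sensing modality and must never share a group
DEFAULT_CONFLICTS = (
    ("Google Nest Hub 2", "Amazon Halo Rise"),
    ("Google Pixel Watch", "Galaxy Watch 5"),
    ("Fitbit Sense 2", "Apple Watch 8"),
)


def default_cohort_config(seed: int = 0) -> CohortConfig:
    """Two-site cohort (37 + 38 participants) with the default roster."""
    sites = (
        SiteConfig("SNUBH", 37, male_prop=27 / 37, age_mean=53.49, age_sd=11.96,
                   bmi_mean=24.64, bmi_sd=4.07, ahi_mean=26.56, ahi_sd=24.25,
                   tib_mean_h=8.01, tib_sd_h=0.31),
        SiteConfig("CLC", 38, male_prop=12 / 38, age_mean=33.95, age_sd=8.07,
                   bmi_mean=23.18, bmi_sd=3.98, ahi_mean=10.02, ahi_sd=10.99,
                   tib_mean_h=6.49, tib_sd_h=0.66),
    )
    return CohortConfig(
        sites=sites,
        devices=default_roster(),
        conflicts=DEFAULT_CONFLICTS,
        seed=seed,
    )


def cohort_config_from_json(path: str | Path) -> CohortConfig:
    """Load a cohort configuration from a JSON file.

    The file may specify ``seed``, ``sites`` (a list of site objects with
    the :class:`SiteConfig` fields) and optionally ``devices`` (objects
    with ``device_id``, ``device_class``, ``emission_matrix``, and the
    optional ``start_offset_s`` / ``epoch_duration`` / ``dropout_prob`` /
    ``groups`` fields).  Omitted sections fall back to the defaults.
    """
    with open(path) as fh:
        raw = json.load(fh)
    base = default_cohort_config(seed=int(raw.get("seed", 0)))
    try:
        sites = (
            tuple(SiteConfig(**site) for site in raw["sites"])
            if "sites" in raw
            else base.sites
        )
        devices = base.devices
        if "devices" in raw:
            specs = []
            for d in raw["devices"]:
                model = DeviceErrorModel(
                    emission_matrix=np.asarray(d["emission_matrix"], dtype=float),
                    start_offset_s=int(d.get("start_offset_s", 0)),
                    epoch_duration=int(d.get("epoch_duration", 30)),
                    dropout_prob=float(d.get("dropout_prob", 0.0)),
                )
                specs.append(
                    DeviceSpec(
                        d["device_id"],
                        d["device_class"],
                        model,
                        groups=tuple(d.get("groups", ("A", "B"))),
                    )
                )
            devices = tuple(specs)
        conflicts = tuple(
            tuple(pair) for pair in raw.get("conflicts", base.conflicts)
        )
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"invalid cohort configuration {path}: {exc}") from exc
    return replace(base, sites=sites, devices=devices, conflicts=conflicts)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_psg(
    params: SleepArchitectureParams, seed: int | np.random.Generator
) -> Hypnogram:
    """Simulate one reference night from the stage-transition chain.

    The epoch count is drawn from the time-in-bed distribution (normal,
    truncated at 1 h); the stage sequence then follows the Markov chain
    from ``initial_stage``.  Deterministic given the seed.
    """
    rng = _as_rng(seed)
    tib_h = max(1.0, rng.normal(params.tib_mean_h, params.tib_sd_h))
    n = max(1, round(tib_h * _S_PER_H / params.epoch_duration))

    cum = np.cumsum(params.transition_matrix, axis=1)
    u = rng.random(n - 1)
    states = np.empty(n, dtype=np.int8)
    states[0] = params.initial_stage
    for i in range(1, n):
        states[i] = np.searchsorted(cum[states[i - 1]], u[i - 1], side="right")
    return Hypnogram(
        source_id="psg",
        start_time=0,
        epoch_duration=params.epoch_duration,
        labels=states,
    )


def simulate_device(
    psg: Hypnogram,
    model: DeviceErrorModel,
    seed: int | np.random.Generator,
    device_id: str = "device",
) -> Hypnogram | None:
    """Simulate one device reading of a reference night (or its dropout).

    With probability ``dropout_prob`` the session is lost (returns None).
    Otherwise the device records on its own epoch grid from
    ``psg.start_time + start_offset_s`` to the reference end; each device
    epoch's label is drawn from the emission matrix conditioned on the
    reference stage at the epoch's midpoint (WAKE outside the reference
    window).  Deterministic given the seed.
    """
    rng = _as_rng(seed)
    if rng.random() < model.dropout_prob:
        return None

    start = psg.start_time + model.start_offset_s
    n_epochs = max(1, -(-(psg.end_time - start) // model.epoch_duration))
    mids = start + np.arange(n_epochs) * model.epoch_duration + model.epoch_duration // 2

    psg_sec = expand_to_seconds(psg)
    rel = mids - psg.start_time
    inside = (rel >= 0) & (rel < psg_sec.size)
    true_stages = np.full(n_epochs, WAKE, dtype=np.int64)
    true_stages[inside] = psg_sec[rel[inside]]

    cum = np.cumsum(model.emission_matrix, axis=1)
    u = rng.random(n_epochs)
    reported = (u[:, None] > cum[true_stages]).sum(axis=1).astype(np.int8)

    return Hypnogram(
        source_id=device_id,
        start_time=start,
        epoch_duration=model.epoch_duration,
        labels=reported,
    )


@dataclass(frozen=True)
class SimulatedCohort:
    """In-memory cohort: manifest plus hypnograms keyed by (session, source)."""

    manifest: pd.DataFrame
    hypnograms: dict[tuple[str, str], Hypnogram]
    vocabularies: dict[str, StageVocabulary]


def simulate_cohort(
    config: CohortConfig, out_dir: str | Path | None = None
) -> SimulatedCohort:
    """Simulate the full two-site cohort; optionally write it to disk.

    Participants alternate between the device groups within each site.
    Files (when ``out_dir`` is given) use the documented CSV/JSON formats:
    ``manifest.csv``, ``hypnograms/<session>_<source>.csv`` and
    ``vocabularies/<device>.json``.  Byte-identical for a given config.
    """
    manifest_rows: list[dict[str, object]] = []
    hypnograms: dict[tuple[str, str], Hypnogram] = {}
    vocabularies = {d.device_id: d.vocabulary() for d in config.devices}

    for site_idx, site in enumerate(config.sites):
        arch = replace(
            config.architecture, tib_mean_h=site.tib_mean_h, tib_sd_h=site.tib_sd_h
        )
        for part_idx in range(site.n_participants):
            participant_id = f"{site.site_id}-P{part_idx + 1:03d}"
            session_id = f"{participant_id}-N1"
            group = config.groups[part_idx % len(config.groups)]

            demo_rng = np.random.default_rng(
                np.random.SeedSequence((config.seed, site_idx, part_idx, 0))
            )
            sex = "male" if demo_rng.random() < site.male_prop else "female"
            age = float(np.clip(demo_rng.normal(site.age_mean, site.age_sd), 19, 70))
            bmi = float(max(14.0, demo_rng.normal(site.bmi_mean, site.bmi_sd)))
            # gamma with the site's AHI mean/SD; strictly non-negative, skewed
            shape = (site.ahi_mean / site.ahi_sd) ** 2
            scale = site.ahi_sd**2 / site.ahi_mean
            ahi = float(demo_rng.gamma(shape, scale))

            psg_rng = np.random.default_rng(
                np.random.SeedSequence((config.seed, site_idx, part_idx, 1))
            )
            psg = simulate_psg(arch, psg_rng)
            hypnograms[(session_id, "psg")] = psg
            base = {
                "session_id": session_id,
                "participant_id": participant_id,
                "site": site.site_id,
                "sex": sex,
                "age": round(age, 1),
                "bmi": round(bmi, 1),
                "ahi": round(ahi, 1),
            }
            manifest_rows.append(
                base
                | {
                    "device_id": "psg",
                    "role": "reference",
                    "device_class": "reference",
                    "hypnogram_path": f"hypnograms/{session_id}_psg.csv",
                }
            )

            for dev_idx, spec in enumerate(config.devices):
                if group not in spec.groups:
                    continue
                dev_rng = np.random.default_rng(
                    np.random.SeedSequence(
                        (config.seed, site_idx, part_idx, 2 + dev_idx)
                    )
                )
                device = simulate_device(
                    psg, spec.error_model, dev_rng, device_id=spec.device_id
                )
                if device is None:
                    continue  # session lost to dropout
                hypnograms[(session_id, spec.device_id)] = device
                slug = spec.device_id.replace(" ", "_")
                manifest_rows.append(
                    base
                    | {
                        "device_id": spec.device_id,
                        "role": "device",
                        "device_class": spec.device_class,
                        "hypnogram_path": f"hypnograms/{session_id}_{slug}.csv",
                    }
                )

    manifest = pd.DataFrame(manifest_rows, columns=list(MANIFEST_COLUMNS))
    cohort = SimulatedCohort(manifest, hypnograms, vocabularies)
    if out_dir is not None:
        _write_cohort(cohort, Path(out_dir))
    return cohort


def _write_cohort(cohort: SimulatedCohort, out_dir: Path) -> None:
    (out_dir / "hypnograms").mkdir(parents=True, exist_ok=True)
    (out_dir / "vocabularies").mkdir(parents=True, exist_ok=True)
    write_manifest(cohort.manifest, out_dir / "manifest.csv")
    write_vocabulary(CANONICAL_VOCABULARY, out_dir / "vocabularies" / "psg.json")
    for device_id, vocab in cohort.vocabularies.items():
        slug = device_id.replace(" ", "_")
        write_vocabulary(vocab, out_dir / "vocabularies" / f"{slug}.json")
    for (session_id, source_id), h in cohort.hypnograms.items():
        slug = source_id.replace(" ", "_")
        vocab = cohort.vocabularies.get(source_id, CANONICAL_VOCABULARY)
        write_hypnogram_csv(
            h, out_dir / "hypnograms" / f"{session_id}_{slug}.csv", vocab
        )
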