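"""End-to-end orchestration: manifest -> aligned pairs -> report bundle.

``run_validation`` binds the whole pipeline together: it reads a session
manifest, standardizes and aligns every device hypnogram to its session's
polysomnography reference on the 1-second grid, tallies per-session
confusion matrices and sleep measures, and aggregates them into the
reporting surfaces (device table, per-site averages, subgroup matrix,
stage margins, Bland-Altman concordance, rank heatmap).  The same core
runs directly on an in-memory :class:`~cstval.simulate.SimulatedCohort`,
which is how the test-suite exercises it without touching disk.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .agreement import confusion_matrix
from .concordance import bland_altman
from .hypnogram import CANONICAL_VOCABULARY, Hypnogram, align_to_reference
from .io import read_hypnogram_csv, read_manifest, read_vocabulary
from .measures import derive_measures
from .report import (
    DEFAULT_SUBGROUP_SPECS,
    Demographics,
    SessionResult,
    StageMargin,
    SubgroupSpec,
    device_table,
    rank_heatmap_matrix,
    round_half_up,
    site_average_macro_f1,
    stage_margin,
    subgroup_column_means,
    subgroup_side_differences,
    subgroup_table,
)
from .simulate import SimulatedCohort, cohort_config_from_json, simulate_cohort

__all__ = [
    "RunConfig",
    "ReportBundle",
    "ManifestError",
    "session_results_from_cohort",
    "build_report",
    "run_validation",
    "run_simulation",
]

logger = logging.getLogger(__name__)

#: the sleep measures compared device-vs-reference, with reporting units
CONCORDANCE_MEASURES = (
    ("se_pct", "sleep_efficiency_pct"),
    ("sol_h", "sleep_latency_min"),
    ("rem_latency_min", "rem_latency_min"),
)


class ManifestError(ValueError):
    """The session manifest violates the pipeline's contract."""


@dataclass(frozen=True)
class RunConfig:
    """Validation-run settings (mirrors the CLI flags)."""

    manifest_path: Path
    vocabulary_dir: Path | None = None
    out_dir: Path | None = None
    pooling_mode: Literal["pooled", "per_participant"] = "pooled"
    subgroup_specs: Sequence[SubgroupSpec] = DEFAULT_SUBGROUP_SPECS
    ttest_variant: Literal["pooled", "welch"] = "welch"
    rounding_decimals: int = 4
    rem_latency_reference: Literal["onset", "start"] = "onset"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        object.__setattr__(self, "manifest_path", Path(self.manifest_path))
        if not self.manifest_path.exists():
            raise FileNotFoundError(f"manifest not found: {self.manifest_path}")
        if self.vocabulary_dir is not None:
            object.__setattr__(self, "vocabulary_dir", Path(self.vocabulary_dir))
        if self.rounding_decimals < 0:
            raise ValueError("rounding_decimals must be non-negative")


@dataclass
class ReportBundle:
    """All aggregated outputs of one validation run."""

    device_table: pd.DataFrame
    stage_table: pd.DataFrame
    subgroup_table: pd.DataFrame
    site_averages: pd.Series
    rank_heatmap: pd.DataFrame
    bland_altman_pairs: pd.DataFrame
    bland_altman_summary: pd.DataFrame
    measures: pd.DataFrame
    headline: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path, decimals: int = 4) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)

        def _rounded(frame: pd.DataFrame) -> pd.DataFrame:
            num = frame.select_dtypes(include=[float]).columns
            rounded = frame.copy()
            rounded[num] = rounded[num].map(lambda v: round_half_up(v, decimals))
            return rounded

        _rounded(self.device_table).to_csv(out / "device_table.csv")
        _rounded(self.stage_table).to_csv(out / "stage_table.csv")
        _rounded(self.subgroup_table).to_csv(out / "subgroup_table.csv")
        self.site_averages.rename("macro_f1").to_csv(out / "site_averages.csv")
        _rounded(self.rank_heatmap).to_csv(out / "rank_heatmap.csv")
        _rounded(self.bland_altman_pairs).to_csv(
            out / "bland_altman_pairs.csv", index=False
        )
        _rounded(self.bland_altman_summary).to_csv(
            out / "bland_altman_summary.csv", index=False
        )
        _rounded(self.measures).to_csv(out / "measures.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(self.headline, fh, indent=1, sort_keys=True)
            fh.write("\n")


def _result_from_pair(
    row: pd.Series,
    psg: Hypnogram,
    device: Hypnogram,
    rem_latency_reference: str,
) -> SessionResult:
    pair = align_to_reference(device, psg)
    logger.info(
        "session %s device %s: discarded_head=%ds padded_head=%ds padded_tail=%ds",
        row["session_id"],
        row["device_id"],
        pair.discarded_head_seconds,
        pair.padded_head_seconds,
        pair.padded_tail_seconds,
    )
    return SessionResult(
        session_id=str(row["session_id"]),
        participant_id=str(row["participant_id"]),
        device_id=str(row["device_id"]),
        device_class=str(row["device_class"]),
        site=str(row["site"]),
        confusion=confusion_matrix(pair),
        measures_device=derive_measures(device, rem_latency_reference),
        measures_reference=derive_measures(psg, rem_latency_reference),
        demographics=Demographics(
            sex=str(row["sex"]),
            age=float(row["age"]),
            bmi=float(row["bmi"]),
            ahi=float(row["ahi"]),
        ),
    )


def _results_from_manifest(
    manifest: pd.DataFrame,
    load_hypnogram,
    rem_latency_reference: str,
) -> list[SessionResult]:
    results: list[SessionResult] = []
    for session_id, rows in manifest.groupby("session_id", sort=True):
        refs = rows[rows["role"] == "reference"]
        if len(refs) != 1:
            raise ManifestError(
                f"session {session_id!r} must have exactly one reference "
                f"hypnogram, found {len(refs)}"
            )
        psg = load_hypnogram(refs.iloc[0])
        for _, row in rows[rows["role"] == "device"].iterrows():
            device = load_hypnogram(row)
            results.append(
                _result_from_pair(row, psg, device, rem_latency_reference)
            )
    return results


def session_results_from_cohort(
    cohort: SimulatedCohort,
    rem_latency_reference: str = "onset",
) -> list[SessionResult]:
    """Score an in-memory simulated cohort into per-session results."""

    def load(row: pd.Series) -> Hypnogram:
        return cohort.hypnograms[(str(row["session_id"]), str(row["device_id"]))]

    return _results_from_manifest(cohort.manifest, load, rem_latency_reference)


def build_report(
    results: Sequence[SessionResult],
    pooling_mode: str = "pooled",
    subgroup_specs: Sequence[SubgroupSpec] = DEFAULT_SUBGROUP_SPECS,
    decimals: int = 4,
) -> ReportBundle:
    """Aggregate per-session results into the full report bundle."""
    if not results:
        raise ValueError("no session results to aggregate")

    overall = device_table(results, mode=pooling_mode)
    sites = sorted({r.site for r in results})
    for site in sites:
        per_site = device_table(results, mode=pooling_mode, site=site)
        overall[f"macro_f1_{site}"] = per_site["macro_f1"]

    stage_cols = [c for c in overall.columns if c.endswith(("_f1", "_sensitivity", "_specificity")) and not c.startswith("macro")]
    stage_table = overall[[c for c in stage_cols if not c.startswith("macro_f1_")]]

    site_averages = pd.Series(
        {
            site: site_average_macro_f1(overall[f"macro_f1_{site}"].dropna())
            for site in sites
        },
        name="macro_f1",
    )

    subgroups = subgroup_table(results, subgroup_specs, mode=pooling_mode)
    column_means = subgroup_column_means(subgroups, decimals)
    side_diffs = subgroup_side_differences(subgroups, subgroup_specs)

    margins: dict[str, StageMargin] = {}
    for stage_name in ("wake", "light", "deep", "rem"):
        if len(overall) >= 2:
            margins[stage_name] = stage_margin(overall[f"{stage_name}_f1"])

    heat_cols = ["macro_f1"] + [f"{s}_f1" for s in ("wake", "light", "deep", "rem")]
    rank_heatmap = rank_heatmap_matrix(overall[heat_cols])

    measures_rows = []
    for r in results:
        for source, m in (
            ("psg", r.measures_reference),
            (r.device_id, r.measures_device),
        ):
            measures_rows.append(
                {
                    "session_id": r.session_id,
                    "source_id": source,
                    "tib_h": m.tib_h,
                    "tst_h": m.tst_h,
                    "sol_h": m.sol_h,
                    "waso_h": m.waso_h,
                    "se_pct": m.se_pct,
                    "rem_latency_min": m.rem_latency_min,
                }
            )
    measures = pd.DataFrame(measures_rows).drop_duplicates(
        subset=["session_id", "source_id"]
    )

    ba_pairs, ba_summary = _bland_altman_tables(results)

    headline = {
        "n_devices": int(len(overall)),
        "n_sessions": int(len({r.session_id for r in results})),
        "site_average_macro_f1": {k: float(v) for k, v in site_averages.items()},
        "subgroup_column_means": {k: float(v) for k, v in column_means.items()},
        "stage_margins": {
            s: {"top": m.top_device, "runner_up": m.runner_up, "margin": m.margin}
            for s, m in margins.items()
        },
        "subgroup_max_variation": {
            var: {
                "device": str(side_diffs[var].idxmax()),
                "difference": round_half_up(float(side_diffs[var].max()), decimals),
            }
            for var in side_diffs.columns
            if side_diffs[var].notna().any()
        },
    }

    return ReportBundle(
        device_table=overall,
        stage_table=stage_table,
        subgroup_table=subgroups,
        site_averages=site_averages,
        rank_heatmap=rank_heatmap,
        bland_altman_pairs=ba_pairs,
        bland_altman_summary=ba_summary,
        measures=measures,
        headline=headline,
    )


def _measure_value(m, key: str) -> float:
    value = getattr(m, key)
    if key == "sol_h":
        return value * 60.0  # report sleep latency in minutes
    return value


def _bland_altman_tables(
    results: Sequence[SessionResult],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    pairs_rows, summary_rows = [], []
    devices = sorted({r.device_id for r in results})
    for device_id in devices:
        sessions = [r for r in results if r.device_id == device_id]
        for key, label in CONCORDANCE_MEASURES:
            dev_vals, ref_vals = [], []
            dropped = 0
            for r in sessions:
                d = _measure_value(r.measures_device, key)
                p = _measure_value(r.measures_reference, key)
                if math.isnan(d) or math.isnan(p):
                    dropped += 1  # measure absent on one side (e.g. no REM)
                    continue
                dev_vals.append(d)
                ref_vals.append(p)
            if dropped:
                logger.info(
                    "bland-altman %s/%s: dropped %d session(s) missing the measure",
                    device_id, label, dropped,
                )
            if len(dev_vals) < 2:
                continue
            res = bland_altman(dev_vals, ref_vals)
            for d, p in zip(dev_vals, ref_vals):
                pairs_rows.append(
                    {
                        "device_id": device_id,
                        "measure": label,
                        "pair_mean": (d + p) / 2.0,
                        "difference": d - p,
                    }
                )
            summary_rows.append(
                {
                    "device_id": device_id,
                    "measure": label,
                    "n": res.n,
                    "n_dropped": dropped,
                    "bias": res.bias,
                    "sd_diff": res.sd_diff,
                    "loa_low": res.loa_low,
                    "loa_high": res.loa_high,
                    "prop_bias_r": res.prop_bias_r,
                    "prop_bias_p": res.prop_bias_p,
                    "prop_bias_significant": res.prop_bias_significant,
                }
            )
    return pd.DataFrame(pairs_rows), pd.DataFrame(summary_rows)


def run_validation(config: RunConfig) -> ReportBundle:
    """Execute the full validation pipeline from a manifest on disk."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    manifest = read_manifest(config.manifest_path)
    base_dir = config.manifest_path.parent
    vocab_dir = config.vocabulary_dir

    def load(row: pd.Series) -> Hypnogram:
        path = base_dir / str(row["hypnogram_path"])
        if not path.exists():
            raise FileNotFoundError(f"hypnogram file not found: {path}")
        device_id = str(row["device_id"])
        vocab = CANONICAL_VOCABULARY
        if vocab_dir is not None:
            vocab_path = Path(vocab_dir) / f"{device_id.replace(' ', '_')}.json"
            if vocab_path.exists():
                vocab = read_vocabulary(vocab_path, device_id)
        return read_hypnogram_csv(path, vocab, source_id=device_id)

    results = _results_from_manifest(
        manifest, load, config.rem_latency_reference
    )
    bundle = build_report(
        results,
        pooling_mode=config.pooling_mode,
        subgroup_specs=config.subgroup_specs,
        decimals=config.rounding_decimals,
    )
    if config.out_dir is not None:
        bundle.write(config.out_dir, config.rounding_decimals)
    return bundle


def run_simulation(
    config_path: str | Path | None, seed: int, out_dir: str | Path
) -> Path:
    """Simulate a cohort to disk; returns the manifest path."""
    from dataclasses import replace as _replace

    if config_path is None:
        from .simulate import default_cohort_config

        config = default_cohort_config(seed=seed)
    else:
        config = _replace(cohort_config_from_json(config_path), seed=seed)
    simulate_cohort(config, out_dir=out_dir)
    return Path(out_dir) / "manifest.csv"
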