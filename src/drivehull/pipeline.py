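"""End-to-end orchestration: simulate → detect → volumes → cohort report.

Each stage reads the previous stage's flat CSV/JSON outputs from the working
directory and writes its own, plus a run log (config echo, counts in/out),
so a full analysis is reproducible from the manifest alone.  The stages are
plain functions; the command-line interface in :mod:`drivehull.cli` is a
thin wrapper around them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort_stats import flag_outliers, histogram_export, log10_compare, summarize
from .drive_detection import DetectionConfig, detect_drives, extract_wrist_segments
from .errors import AccelIOError, DriveHullError
from .hullvolume import (
    ParticipantVolume,
    TrimConfig,
    hull_evolution,
    participant_volume,
    trim_centiles,
)
from .io_accel import AccelSeries, align_pair, read_accel_csv
from .synthetic import SimulationParams, simulate_cohort

log = logging.getLogger("drivehull")

#: quarters, matching the usual per-drive hull-development view
EVOLUTION_SLICES = 4


@dataclass
class PipelineConfig:
    """Composed configuration of a full pipeline run."""

    detection: DetectionConfig = field(default_factory=DetectionConfig)
    trim: TrimConfig = field(default_factory=TrimConfig)
    sim: SimulationParams = field(default_factory=SimulationParams)
    aggregation: str = "pooled"
    offset_s: dict[str, float] = field(default_factory=dict)
    input_dir: str = "cohort_input"
    output_dir: str = "cohort_output"
    n_evolution_slices: int = EVOLUTION_SLICES

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        if "detection" in raw:
            kwargs["detection"] = DetectionConfig(**raw["detection"])
        if "trim" in raw:
            kwargs["trim"] = TrimConfig(**raw["trim"])
        if "sim" in raw:
            sim = dict(raw["sim"])
            for key in (
                "drive_duration_s_range",
                "event_magnitude_range_g",
                "event_duration_s_range",
                "maneuver_amplitude_range_g",
                "wrist_burst_duration_s_range",
            ):
                if key in sim:
                    sim[key] = tuple(sim[key])
            kwargs["sim"] = SimulationParams(**sim)
        for key in (
            "aggregation",
            "offset_s",
            "input_dir",
            "output_dir",
            "n_evolution_slices",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ParticipantResult:
    """Everything the per-participant analysis produced."""

    volume: ParticipantVolume | None
    segments: list
    n_retained: int
    evolution: list[tuple[int, int, float]]  # (drive_id, slice_index, cum vol)


def analyze_pair(
    wrist: AccelSeries,
    vehicle: AccelSeries,
    config: PipelineConfig | None = None,
    offset_s: float = 0.0,
) -> ParticipantResult:
    """Run detection + hull volumes for one aligned wrist/vehicle pair.

    Hull volumes are computed on the *raw* (gravity-included) trimmed
    acceleration coordinates of both devices; the detrended signal is used
    only to detect drives and score events.
    """
    config = config or PipelineConfig()
    pair = align_pair(wrist, vehicle, offset_s)
    segments, _detrended, _offsets = detect_drives(pair.vehicle, config.detection)
    wrist_subs, retained = extract_wrist_segments(pair.wrist, segments)

    evolution: list[tuple[int, int, float]] = []
    if not retained:
        return ParticipantResult(None, segments, 0, evolution)

    wrist_clouds = [s.xyz for s in wrist_subs]
    vehicle_clouds = [
        pair.vehicle.crop(seg.start_s, seg.end_s).xyz for seg in retained
    ]
    volume = participant_volume(
        wrist.participant_id,
        wrist_clouds,
        vehicle_clouds,
        drive_ids=[seg.drive_id for seg in retained],
        aggregation=config.aggregation,
        trim=config.trim,
    )
    for seg, sub in zip(retained, wrist_subs):
        trimmed = trim_centiles(sub.xyz, config.trim)
        for k, res in enumerate(hull_evolution(trimmed, config.n_evolution_slices)):
            evolution.append((seg.drive_id, k, res.volume_g3))
    return ParticipantResult(volume, segments, len(retained), evolution)


# ---------------------------------------------------------------------------
# stages


def _write_run_log(out_dir: Path, stage: str, config: PipelineConfig, info: dict) -> None:
    payload = {"stage": stage, "config_hash": config.config_hash(), **info}
    (out_dir / f"run_log_{stage}.json").write_text(json.dumps(payload, indent=2))


def run_simulate(config: PipelineConfig) -> Path:
    """Stage 1: write the synthetic cohort into ``input_dir``."""
    out = Path(config.input_dir)
    manifest, _ = simulate_cohort(config.sim, out)
    log.info("simulated %d participants into %s", len(manifest["participants"]), out)
    return out / "manifest.json"


def _load_manifest(config: PipelineConfig) -> list[dict]:
    manifest_path = Path(config.input_dir) / "manifest.json"
    if manifest_path.is_file():
        return json.loads(manifest_path.read_text())["participants"]
    # fall back to filename convention <pid>_wrist.csv / <pid>_vehicle.csv
    entries = []
    for wrist_file in sorted(Path(config.input_dir).glob("*_wrist.csv")):
        pid = wrist_file.name[: -len("_wrist.csv")]
        vehicle_file = wrist_file.with_name(f"{pid}_vehicle.csv")
        if vehicle_file.is_file():
            entries.append(
                {
                    "participant_id": pid,
                    "wrist": str(wrist_file),
                    "vehicle": str(vehicle_file),
                }
            )
    if not entries:
        raise AccelIOError(f"no input series found in {config.input_dir}")
    return entries


def run_detect_and_volumes(config: PipelineConfig) -> pd.DataFrame:
    """Stages 2+3: detection and hull volumes for every manifest participant.

    Writes ``segments.csv``, ``volumes.csv``, ``drive_volumes.csv`` and
    ``evolution.csv`` under ``output_dir``; returns the volumes table.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seg_rows, vol_rows, drive_rows, evo_rows = [], [], [], []
    n_skipped = 0
    base = Path(config.input_dir)
    for entry in _load_manifest(config):
        pid = entry["participant_id"]
        wrist, _ = read_accel_csv(base / entry["wrist"], "wrist", pid)
        vehicle, _ = read_accel_csv(base / entry["vehicle"], "vehicle", pid)
        result = analyze_pair(
            wrist, vehicle, config, offset_s=config.offset_s.get(pid, 0.0)
        )
        for seg in result.segments:
            seg_rows.append(
                {
                    "participant_id": pid,
                    "drive_id": seg.drive_id,
                    "start_s": seg.start_s,
                    "end_s": seg.end_s,
                    "duration_s": seg.duration_s,
                    "peak_long_accel_g": seg.peak_long_accel_g,
                    "peak_long_decel_g": seg.peak_long_decel_g,
                    "peak_lateral_abs_g": seg.peak_lateral_abs_g,
                    "retained": seg.retained,
                }
            )
        if result.volume is None:
            n_skipped += 1
            log.warning("participant %s: no retained drives, skipped", pid)
            continue
        pv = result.volume
        for role, vol in (
            ("wrist", pv.wrist_volume_g3),
            ("vehicle", pv.vehicle_volume_g3),
        ):
            vol_rows.append(
                {
                    "participant_id": pid,
                    "device_role": role,
                    "aggregation": pv.aggregation,
                    "volume_g3": vol,
                    "n_drives": pv.n_drives,
                }
            )
        for drive_id, wvol, vvol in pv.per_drive_volumes:
            drive_rows.append(
                {
                    "participant_id": pid,
                    "drive_id": drive_id,
                    "wrist_volume_g3": wvol,
                    "vehicle_volume_g3": vvol,
                }
            )
        for drive_id, k, cum in result.evolution:
            evo_rows.append(
                {
                    "participant_id": pid,
                    "drive_id": drive_id,
                    "slice_index": k,
                    "cumulative_volume_g3": cum,
                }
            )

    volumes = pd.DataFrame(vol_rows)
    pd.DataFrame(seg_rows).to_csv(out / "segments.csv", index=False)
    volumes.to_csv(out / "volumes.csv", index=False)
    pd.DataFrame(drive_rows).to_csv(out / "drive_volumes.csv", index=False)
    pd.DataFrame(evo_rows).to_csv(out / "evolution.csv", index=False)
    _write_run_log(
        out,
        "volumes",
        config,
        {
            "n_participants_in": len(_load_manifest(config)),
            "n_participants_with_volumes": volumes["participant_id"].nunique()
            if len(volumes)
            else 0,
            "n_skipped_no_retained_drives": n_skipped,
        },
    )
    return volumes


def run_cohort(config: PipelineConfig) -> dict:
    """Stage 4: cohort descriptive report from ``volumes.csv``.

    Writes ``cohort_report.json``, a statistics-by-device CSV and histogram
    data for the wrist-volume distribution; returns the report dict.
    """
    out = Path(config.output_dir)
    vol_path = out / "volumes.csv"
    if not vol_path.is_file():
        raise AccelIOError(f"missing {vol_path}; run the volumes stage first")
    volumes = pd.read_csv(vol_path)
    report: dict = {"summaries": {}, "outliers": {}}
    table_rows = {}
    for role in ("wrist", "vehicle"):
        sub = volumes[volumes["device_role"] == role]
        vals = sub["volume_g3"].to_numpy()
        if np.all(vals > 0):
            raw, logged = log10_compare(vals, role)
            report["summaries"][f"{role}_log10"] = dataclasses.asdict(logged)
        else:
            raw = summarize(vals, role)
        report["summaries"][role] = dataclasses.asdict(raw)
        flags = flag_outliers(
            list(zip(sub["participant_id"], sub["volume_g3"])), raw
        )
        report["outliers"][role] = [pid for pid, f in flags if f]
        table_rows[role] = raw

    stats_csv = pd.DataFrame(
        {
            "Measure": [
                "Mean",
                "Median",
                "Standard Deviation",
                "Min",
                "Max",
                "IQR",
                "Upper Outlier Threshold",
            ],
            **{
                f"{role.capitalize()} Movement Volume": [
                    table_rows[role].mean,
                    table_rows[role].median,
                    table_rows[role].sd,
                    table_rows[role].min,
                    table_rows[role].max,
                    table_rows[role].iqr,
                    table_rows[role].upper_outlier_threshold,
                ]
                for role in table_rows
            },
        }
    )
    stats_csv.to_csv(out / "cohort_report.csv", index=False)

    wrist_vals = volumes[volumes["device_role"] == "wrist"]["volume_g3"].to_numpy()
    edges, counts = histogram_export(wrist_vals)
    pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    ).to_csv(out / "wrist_volume_histogram.csv", index=False)

    (out / "cohort_report.json").write_text(json.dumps(report, indent=2))
    _write_run_log(out, "cohort", config, {"n_rows": len(volumes)})
    return report


def run_all(config: PipelineConfig) -> dict:
    """simulate → detect → volumes → cohort, returning the cohort report."""
    run_simulate(config)
    run_detect_and_volumes(config)
    return run_cohort(config)
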