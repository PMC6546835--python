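"""Configured, seeded end-to-end pipeline: simulate → segment → quantify →
profile → kinetics → report.

A single structured config (YAML/JSON mapping) drives everything; re-running
with the same config and seed reproduces the result tables byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from importlib import metadata
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .errors import CalibrationError, ConfigError, UndefinedStatisticError
from .imaging import write_stack, z_project
from .kinetics import GroupComparison, KillEvent, compare_groups, extract_kill_events
from .quantify import CellCalibration, calibrate, load_calibration
from .regions import ConditionSummary, SubRegionProfile, aggregate, overall_percent_killed, profile
from .segmentation import classify_dead, components_to_mask, label_components, segment_channel
from .synth import GroundTruth, SceneParams, TimeLapseParams, generate_scene, generate_timelapse, write_truth

log = logging.getLogger("cytoprof")

_SCENE_KEYS = {f.name for f in dataclasses.fields(SceneParams)} - {"seed"}
_TIMELAPSE_KEYS = {f.name for f in dataclasses.fields(TimeLapseParams)} - {"seed"}

_THRESHOLD_DOMAINS: dict[str, tuple[float, float]] = {
    # key -> inclusive (lo, hi); None bounds handled separately
    "overlap_fraction": (0.0, 1.0),
    "onset_fraction": (0.0, 1.0),
    "blank_guard": (0.0, 1.0),
}

_DEFAULT_THRESHOLDS: dict[str, Any] = {
    "overlap_fraction": 0.5,
    "onset_fraction": 0.3,
    "persistence": 2,
    "contact_dilation": 1,
    "min_area": None,  # default: 25% of calibrated mean live target area
    "max_step": 20.0,
    "blank_guard": 0.45,
}


@dataclass
class ConditionSpec:
    label: str
    scene: dict[str, Any] = field(default_factory=dict)
    timelapse: dict[str, Any] | None = None


@dataclass
class PipelineConfig:
    """Validated pipeline configuration with all defaults filled in."""

    seed: int = 0
    output_dir: str = "cytoprof_out"
    n_replicates: int = 3
    roi: dict[str, float] = field(default_factory=lambda: {"side_length": 700.0, "bin_width": 100.0})
    thresholds: dict[str, Any] = field(default_factory=lambda: dict(_DEFAULT_THRESHOLDS))
    scene: dict[str, Any] = field(default_factory=dict)
    timelapse: dict[str, Any] | None = None
    conditions: list[ConditionSpec] = field(default_factory=list)
    calibration_path: str | None = None
    write_images: bool = True

    def scene_params(self, condition: ConditionSpec, seed: int) -> SceneParams:
        kwargs = {**self.scene, **condition.scene}
        kwargs.setdefault("roi_side_length", self.roi["side_length"])
        kwargs.setdefault("roi_bin_width", self.roi["bin_width"])
        return SceneParams(seed=seed, **kwargs)

    def timelapse_params(self, condition: ConditionSpec, seed: int) -> TimeLapseParams | None:
        if self.timelapse is None and condition.timelapse is None:
            return None
        kwargs = {**self.scene, **condition.scene,
                  **(self.timelapse or {}), **(condition.timelapse or {})}
        kwargs.setdefault("roi_side_length", self.roi["side_length"])
        kwargs.setdefault("roi_bin_width", self.roi["bin_width"])
        return TimeLapseParams(seed=seed, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["roi"]["n_bins"] = round(self.roi["side_length"] / self.roi["bin_width"])
        return d


def _check_mapping(raw: Any, allowed: set[str], where: str) -> dict[str, Any]:
    if raw is None:
        return {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{where} must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}; allowed: {sorted(allowed)}")
    return dict(raw)


def validate_config(source: str | dict[str, Any]) -> PipelineConfig:
    """Parse and validate a pipeline config (YAML text or mapping).

    Fills defaults, checks every threshold against its documented domain,
    and rejects unknown keys with a message naming the key.
    """
    raw = yaml.safe_load(source) if isinstance(source, str) else source
    if raw is None:
        raw = {}
    top_allowed = {"seed", "output_dir", "n_replicates", "roi", "thresholds",
                   "scene", "timelapse", "conditions", "calibration_path",
                   "write_images"}
    raw = _check_mapping(raw, top_allowed, "config")

    roi = {"side_length": 700.0, "bin_width": 100.0}
    roi.update(_check_mapping(raw.get("roi"), {"side_length", "bin_width"}, "roi"))
    if roi["side_length"] <= 0 or roi["bin_width"] <= 0:
        raise ConfigError("roi.side_length and roi.bin_width must be > 0")
    ratio = roi["side_length"] / roi["bin_width"]
    if abs(ratio - round(ratio)) > 1e-9:
        raise ConfigError(
            f"roi.side_length must be an integral multiple of roi.bin_width, "
            f"got {roi['side_length']} / {roi['bin_width']}"
        )

    thresholds = dict(_DEFAULT_THRESHOLDS)
    thresholds.update(_check_mapping(raw.get("thresholds"), set(_DEFAULT_THRESHOLDS), "thresholds"))
    for key, (lo, hi) in _THRESHOLD_DOMAINS.items():
        v = thresholds[key]
        if not (isinstance(v, (int, float)) and lo <= v <= hi):
            raise ConfigError(f"thresholds.{key} must be in [{lo}, {hi}], got {v!r}")
    for key in ("persistence", "contact_dilation"):
        if not (isinstance(thresholds[key], int) and thresholds[key] >= 0):
            raise ConfigError(f"thresholds.{key} must be a non-negative integer, got {thresholds[key]!r}")
    if thresholds["max_step"] <= 0:
        raise ConfigError(f"thresholds.max_step must be > 0, got {thresholds['max_step']!r}")
    if thresholds["min_area"] is not None and thresholds["min_area"] < 0:
        raise ConfigError(f"thresholds.min_area must be >= 0 or null, got {thresholds['min_area']!r}")

    scene = _check_mapping(raw.get("scene"), _SCENE_KEYS, "scene")
    timelapse = raw.get("timelapse")
    if timelapse is not None:
        timelapse = _check_mapping(timelapse, _TIMELAPSE_KEYS, "timelapse")

    conditions: list[ConditionSpec] = []
    for i, entry in enumerate(raw.get("conditions") or []):
        entry = _check_mapping(entry, {"label", "scene", "timelapse"}, f"conditions[{i}]")
        label = str(entry.get("label", f"condition_{i}"))
        cscene = _check_mapping(entry.get("scene"), _SCENE_KEYS, f"conditions[{i}].scene")
        ctl = entry.get("timelapse")
        if ctl is not None:
            ctl = _check_mapping(ctl, _TIMELAPSE_KEYS, f"conditions[{i}].timelapse")
        conditions.append(ConditionSpec(label=label, scene=cscene, timelapse=ctl))
    if not conditions:
        conditions = [ConditionSpec(label="default")]

    n_replicates = raw.get("n_replicates", 3)
    if not (isinstance(n_replicates, int) and n_replicates >= 1):
        raise ConfigError(f"n_replicates must be an integer >= 1, got {n_replicates!r}")
    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        raise ConfigError(f"seed must be an integer, got {seed!r}")

    config = PipelineConfig(
        seed=seed,
        output_dir=str(raw.get("output_dir", "cytoprof_out")),
        n_replicates=n_replicates,
        roi=roi,
        thresholds=thresholds,
        scene=scene,
        timelapse=timelapse,
        conditions=conditions,
        calibration_path=raw.get("calibration_path"),
        write_images=bool(raw.get("write_images", True)),
    )
    # surface SceneParams domain errors (e.g. dead_fraction 1.5) at validation
    for cond in conditions:
        config.scene_params(cond, seed)
        config.timelapse_params(cond, seed)
    return config


@dataclass
class AssayReport:
    """Everything the pipeline measured, plus provenance."""

    summaries: list[ConditionSummary]
    overall_percent_killed: dict[str, float | None]
    profiles: list[SubRegionProfile]
    events: dict[str, list[KillEvent]]
    comparisons: list[GroupComparison]
    provenance: dict[str, Any]

    def to_dict(self) -> dict[str, Any]:
        return {
            "overall_percent_killed": self.overall_percent_killed,
            "summaries": [
                s.to_frame().to_dict(orient="records") for s in self.summaries
            ],
            "kill_events": {
                label: [dataclasses.asdict(e) for e in evs]
                for label, evs in self.events.items()
            },
            "comparisons": [
                {
                    "group_a": c.label_a,
                    "group_b": c.label_b,
                    "n_a": len(c.times_a),
                    "n_b": len(c.times_b),
                    "mean_a_min": c.mean_a,
                    "mean_b_min": c.mean_b,
                    "t_statistic": c.t_statistic,
                    "degrees_of_freedom": c.degrees_of_freedom,
                    "p_value": c.p_value,
                }
                for c in self.comparisons
            ],
            "provenance": self.provenance,
        }


def calibration_from_truth(truth: GroundTruth, params: SceneParams) -> CellCalibration:
    """Self-consistent calibration from the generator's rendered areas.

    Mirrors the manual single-cell selection protocol on synthetic data;
    cell types absent from the scene fall back to the generator's nominal
    mean areas so downstream formulas stay defined.
    """
    eff = [c.rendered_area for c in truth.effectors() if c.rendered_area > 0]
    live = [c.rendered_area for c in truth.targets()
            if c.state == "live" and c.rendered_area > 0]
    dead = [c.rendered_area for c in truth.targets()
            if c.state == "dead" and c.rendered_area > 0]
    return calibrate(
        eff or [params.effector_area_mean],
        live or [params.live_area_mean],
        dead or [params.dead_area_mean],
    )


def quantify_scene(
    channels: dict[str, Any],
    calibration: CellCalibration,
    roi,
    thresholds: dict[str, Any],
    condition: str = "",
    replicate: int = 0,
) -> tuple[SubRegionProfile, float | None]:
    """Segment one scene's channels and compute its profile + pooled stat."""
    ps = channels["target"].pixel_size
    guard = thresholds["blank_guard"]
    min_area = thresholds["min_area"]

    def _min_area(mean_cell_area: float) -> float:
        # debris suppression: default cutoff is 25% of the mean cell area
        return 0.25 * mean_cell_area if min_area is None else min_area

    def _clean(img, mean_cell_area: float):
        mask = segment_channel(img, ps, guard)
        comps = label_components(mask, min_area=_min_area(mean_cell_area))
        return components_to_mask(comps, mask.pixels.shape, ps)

    imgs = {name: z_project(stack, "max") for name, stack in channels.items()}
    eff_mask = _clean(imgs["effector"], calibration.mean_effector_area)
    tgt_mask = segment_channel(imgs["target"], ps, guard)
    dead_mask = _clean(imgs["dead_stain"], calibration.mean_dead_target_area)
    comps = label_components(tgt_mask, min_area=_min_area(calibration.mean_dead_target_area))
    classified = classify_dead(comps, dead_mask, tgt_mask.pixels.shape,
                               thresholds["overlap_fraction"])
    prof = profile(eff_mask, classified.live_mask, classified.dead_mask, roi,
                   calibration, condition=condition, replicate=replicate)
    try:
        overall = overall_percent_killed(classified.live_mask, classified.dead_mask,
                                         roi, calibration)
    except UndefinedStatisticError:
        overall = None
    return prof, overall


def run(config: PipelineConfig, output_dir: str | Path | None = None) -> AssayReport:
    """Execute the full pipeline and write all stage outputs.

    Per condition and replicate: generate a scene, segment it, and build a
    depth profile; optionally generate a time-lapse and score kill events.
    Conditions with scored events are compared pairwise with the pooled
    t-test.  All tables land in `output_dir` along with ``report.json``.
    """
    out = Path(output_dir if output_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.perf_counter()

    fixed_calibration = (
        load_calibration(config.calibration_path) if config.calibration_path else None
    )

    profiles: list[SubRegionProfile] = []
    summaries: list[ConditionSummary] = []
    overall: dict[str, float | None] = {}
    events: dict[str, list[KillEvent]] = {}
    calibration_used: CellCalibration | None = fixed_calibration

    for ci, cond in enumerate(config.conditions):
        stage_t = time.perf_counter()
        cond_profiles: list[SubRegionProfile] = []
        cond_overall: list[float] = []
        for rep in range(config.n_replicates):
            seed = config.seed + 1000 * ci + rep
            params = config.scene_params(cond, seed)
            channels, truth = generate_scene(params)
            if config.write_images:
                img_dir = out / "images" / cond.label / f"rep{rep}"
                for name, stack in channels.items():
                    write_stack(stack, img_dir / f"{name}.tif")
                write_truth(truth, img_dir / "truth.csv")
            calibration = fixed_calibration or calibration_from_truth(truth, params)
            calibration_used = calibration
            prof, ov = quantify_scene(channels, calibration, truth.roi,
                                      config.thresholds, cond.label, rep)
            cond_profiles.append(prof)
            if ov is not None:
                cond_overall.append(ov)
        profiles.extend(cond_profiles)
        summaries.append(aggregate(cond_profiles))
        overall[cond.label] = (
            sum(cond_overall) / len(cond_overall) if cond_overall else None
        )
        log.info("condition %s: %d replicates profiled in %.2fs", cond.label,
                 config.n_replicates, time.perf_counter() - stage_t)

        tl_params = config.timelapse_params(cond, config.seed + 1000 * ci + 500)
        if tl_params is not None:
            stage_t = time.perf_counter()
            movie, truth_events = generate_timelapse(tl_params)
            if config.write_images:
                write_truth(truth_events, out / "images" / cond.label / "events_truth.csv")
            calib = fixed_calibration
            min_area = config.thresholds["min_area"]
            if min_area is None:
                min_area = 0.25 * (calib.mean_live_target_area if calib
                                   else tl_params.live_area_mean)
            events[cond.label] = extract_kill_events(
                movie,
                min_area=min_area,
                max_step=config.thresholds["max_step"],
                contact_dilation=config.thresholds["contact_dilation"],
                onset_fraction=config.thresholds["onset_fraction"],
                persistence=config.thresholds["persistence"],
                blank_guard=config.thresholds["blank_guard"],
            )
            log.info("condition %s: %d kill events scored in %.2fs", cond.label,
                     len(events[cond.label]), time.perf_counter() - stage_t)

    comparisons: list[GroupComparison] = []
    labels = [l for l, evs in events.items() if len(evs) >= 2]
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            comparisons.append(compare_groups(
                [e.time_for_killing for e in events[labels[i]]],
                [e.time_for_killing for e in events[labels[j]]],
                labels[i], labels[j],
            ))

    config_dict = config.to_dict()
    config_json = json.dumps(config_dict, sort_keys=True, default=str)
    try:
        version = metadata.version("cytoprof")
    except metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"
    provenance = {
        "config": config_dict,
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "seed": config.seed,
        "software": {"name": "cytoprof", "version": version},
        "runtime_s": round(time.perf_counter() - t_start, 3),
    }
    report = AssayReport(
        summaries=summaries,
        overall_percent_killed=overall,
        profiles=profiles,
        events=events,
        comparisons=comparisons,
        provenance=provenance,
    )
    _write_report(report, calibration_used, out)
    return report


def _write_report(report: AssayReport, calibration: CellCalibration | None,
                  out: Path) -> None:
    pd.concat([p.to_frame() for p in report.profiles], ignore_index=True).to_csv(
        out / "profiles.csv", index=False
    )
    pd.concat([s.to_frame() for s in report.summaries], ignore_index=True).to_csv(
        out / "summaries.csv", index=False
    )
    event_rows = [
        {
            "condition": label,
            "effector_id": e.effector_track_id,
            "target_id": e.target_track_id,
            "contact_time_min": e.contact_time,
            "pi_time_min": e.pi_time,
            "time_for_killing_min": e.time_for_killing,
        }
        for label, evs in report.events.items()
        for e in evs
    ]
    pd.DataFrame(
        event_rows,
        columns=["condition", "effector_id", "target_id", "contact_time_min",
                 "pi_time_min", "time_for_killing_min"],
    ).to_csv(out / "events.csv", index=False)
    if calibration is not None:
        pd.DataFrame(
            [
                {"cell_type": "effector", "mean_area_um2": calibration.mean_effector_area,
                 "n": calibration.n_cells_per_type.get("effector")},
                {"cell_type": "live_target", "mean_area_um2": calibration.mean_live_target_area,
                 "n": calibration.n_cells_per_type.get("live_target")},
                {"cell_type": "dead_target", "mean_area_um2": calibration.mean_dead_target_area,
                 "n": calibration.n_cells_per_type.get("dead_target")},
            ]
        ).to_csv(out / "calibration.csv", index=False)
    # provenance holds a wall-clock runtime; everything else is deterministic
    (out / "report.json").write_text(
        json.dumps(report.to_dict(), indent=2, default=_json_default) + "\n"
    )


def _json_default(obj: Any):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
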