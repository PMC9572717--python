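"""End-to-end orchestration: align -> reconstruct -> metrics -> report.

A pipeline run consumes the four input files (two timestamp logs, the pose
CSV, the depth stack), executes the three processing stages in order and
emits a report bundle: the metrics report (JSON + flat CSV), per-stage QC
tables, and a run manifest (config echo, package version, input digests)
sufficient to re-run the identical analysis. Runs are deterministic:
identical inputs and config produce byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from gm3d import __version__
from gm3d.depth_reconstruction import (ReconstructionParams,
                                       reconstruct_trajectories,
                                       write_reconstruction_qc)
from gm3d.formats_io import (default_camera, CameraModel, read_depth_stack,
                             read_pose_csv, read_timestamps_csv,
                             write_metrics_report)
from gm3d.gm_metrics import MetricsConfig, compute_all_metrics
from gm3d.stream_sync import align_streams, write_alignment_csv

log = logging.getLogger("gm3d")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config",
           "validate_config"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for the log and exit path."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything one pipeline invocation needs, loadable from YAML."""

    rgb_timestamps: Path
    depth_timestamps: Path
    pose: Path
    depth: Path
    output_dir: Path
    camera: CameraModel = field(default_factory=default_camera)
    reconstruction: ReconstructionParams = field(default_factory=ReconstructionParams)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    alignment_tolerance_ms: float | None = None  # None -> half nominal interval
    log_level: str = "INFO"

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("rgb_timestamps", "depth_timestamps", "pose", "depth",
                  "output_dir"):
            d[k] = str(d[k])
        d["camera"]["rgb_resolution"] = list(d["camera"]["rgb_resolution"])
        d["camera"]["depth_resolution"] = list(d["camera"]["depth_resolution"])
        return d


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline config."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return _config_from_dict(raw, base=Path(path).parent)


def _config_from_dict(raw: dict, base: Path) -> PipelineConfig:
    problems: list[str] = []
    inputs = raw.get("inputs", {})
    paths = {}
    for key in ("rgb_timestamps", "depth_timestamps", "pose", "depth"):
        if key not in inputs:
            problems.append(f"inputs.{key} is required")
            continue
        p = Path(inputs[key])
        if not p.is_absolute():
            p = base / p
        paths[key] = p
    if "output_dir" not in raw:
        problems.append("output_dir is required")
    kwargs: dict = {}
    try:
        cam = raw.get("camera")
        if cam:
            cam = dict(cam)
            for rk in ("rgb_resolution", "depth_resolution"):
                if rk in cam:
                    cam[rk] = tuple(cam[rk])
            kwargs["camera"] = CameraModel(**cam)
    except (TypeError, ValueError) as exc:
        problems.append(f"camera: {exc}")
    for section, cls, key in (("reconstruction", ReconstructionParams, "reconstruction"),
                              ("metrics", MetricsConfig, "metrics")):
        try:
            if section in raw:
                kwargs[key] = cls(**raw[section])
        except (TypeError, ValueError) as exc:
            problems.append(f"{section}: {exc}")
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    out = Path(raw["output_dir"])
    if not out.is_absolute():
        out = base / out
    return PipelineConfig(
        output_dir=out,
        alignment_tolerance_ms=raw.get("alignment_tolerance_ms"),
        log_level=raw.get("log_level", "INFO"),
        **paths, **kwargs)


def validate_config(path: str | Path) -> list[str]:
    """Return a list of problems (empty when the config is runnable)."""
    try:
        cfg = load_config(path)
    except (ValueError, TypeError, yaml.YAMLError) as exc:
        return [str(exc)]
    problems = []
    for key in ("rgb_timestamps", "depth_timestamps", "pose", "depth"):
        p = getattr(cfg, key)
        if not Path(p).exists():
            problems.append(f"inputs.{key}: {p} does not exist")
    return problems


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute the full chain and write the report bundle.

    Returns the map of emitted paths. On a stage failure a
    :class:`PipelineError` is raised after writing a FAILED marker next to
    any partial outputs.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    try:
        stage = "read_inputs"
        rgb_ts = read_timestamps_csv(config.rgb_timestamps, "rgb")
        depth_ts = read_timestamps_csv(config.depth_timestamps, "depth")
        track = read_pose_csv(config.pose)
        depth = read_depth_stack(config.depth)
        digests = {k: _sha256(getattr(config, k))
                   for k in ("rgb_timestamps", "depth_timestamps", "pose")}

        stage = "alignment"
        align = align_streams(rgb_ts, depth_ts, config.alignment_tolerance_ms)
        paths["alignment_qc"] = out / "alignment_qc.csv"
        write_alignment_csv(align, paths["alignment_qc"])
        log.info("alignment: %d slots, %d RGB gaps, %d depth gaps",
                 align.n_slots, align.inserted_rgb_gaps.size,
                 align.inserted_depth_gaps.size)

        stage = "reconstruction"
        traj = reconstruct_trajectories(track, depth, align, config.camera,
                                        config.reconstruction)
        paths["reconstruction_qc"] = out / "reconstruction_qc.csv"
        write_reconstruction_qc(traj, paths["reconstruction_qc"])
        for warning in traj.warnings:
            log.warning("reconstruction: %s", warning)
        for poi, counts in traj.removal_counts.items():
            log.info("reconstruction %s: %s", poi,
                     ", ".join(f"{k}={v}" for k, v in counts.items() if v))

        stage = "metrics"
        metrics = compute_all_metrics(traj, config.metrics)
        json_path, csv_path = write_metrics_report(metrics, out / "metrics")
        paths["metrics_json"] = json_path
        paths["metrics_csv"] = csv_path
        for side, bout in metrics.bouts.items():
            if bout is not None:
                log.info("bouts %s: n=%d, movement=%.1f%%", side,
                         bout.n_bouts, bout.movement_pct)

        stage = "manifest"
        manifest = {
            "version": __version__,
            "config": config.echo(),
            "input_digests": digests,
            "alignment": {
                "n_slots": align.n_slots,
                "rgb_gaps": int(align.inserted_rgb_gaps.size),
                "depth_gaps": int(align.inserted_depth_gaps.size),
            },
            "reconstruction": {
                "removal_counts": traj.removal_counts,
                "warnings": traj.warnings,
                "usable": {poi: bool(u) for poi, u
                           in zip(traj.poi_names, traj.usable)},
            },
        }
        paths["manifest"] = out / "manifest.json"
        paths["manifest"].write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc
    return paths


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
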