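"""Domain containers and file I/O for every external format the pipeline touches.

External representations
------------------------
* pose-track CSV in the DeepLabCut dialect (three header rows
  scorer / bodyparts / coords, then one row per frame with x, y, likelihood
  triplets per bodypart);
* depth frames as a 16-bit single-channel PNG sequence named by frame index,
  or a raw binary stack with a small text sidecar;
* per-stream timestamp logs as two-column CSV (frame_index, time_ms);
* the metrics report as JSON plus a flat one-row CSV.

Units are never rescaled by readers or writers: depth stays in millimetres,
confidence stays in [0, 1], pixel coordinates are 0-based (origin top-left)
and may be sub-pixel.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import imageio.v3 as iio

#: Canonical order of the six tracked points of interest: left/right
#: shoulder, elbow and wrist.
POI_NAMES: tuple[str, ...] = ("LS", "RS", "LE", "RE", "LW", "RW")

#: Nominal frame interval of both streams at ~30 fps, in milliseconds.
NOMINAL_DT_MS: float = 1000.0 / 30.0


class FormatError(ValueError):
    """A file does not conform to the expected external dialect."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class TimestampSeries:
    """Per-stream frame times in milliseconds.

    Frame rates of consumer RGB-D sensors are only nominally constant; the
    measured per-frame timestamps are what the alignment stage consumes.

    Parameters
    ----------
    stream_id:
        Either ``"rgb"`` or ``"depth"``.
    times_ms:
        Strictly increasing frame times in milliseconds, length >= 2.
    nominal_dt_ms:
        Nominal sampling interval (default 1000/30 ms); half of it is the
        default alignment tolerance.
    """

    stream_id: str
    times_ms: np.ndarray
    nominal_dt_ms: float = NOMINAL_DT_MS

    def __post_init__(self) -> None:
        if self.stream_id not in ("rgb", "depth"):
            raise ValueError(f"stream_id must be 'rgb' or 'depth', got {self.stream_id!r}")
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.times_ms.ndim != 1 or self.times_ms.size < 2:
            raise ValueError("times_ms must be a 1-D sequence of length >= 2")
        if not np.all(np.diff(self.times_ms) > 0):
            raise ValueError(f"{self.stream_id} timestamps must be strictly increasing")
        if not self.nominal_dt_ms > 0:
            raise ValueError("nominal_dt_ms must be positive")

    def __len__(self) -> int:
        return int(self.times_ms.size)


@dataclass
class Pose2DTrack:
    """Per-frame 2D coordinates and confidence for the six points of interest.

    ``u``, ``v`` and ``confidence`` are ``(n_frames, n_poi)`` arrays; pixel
    coordinates are 0-based in the RGB resolution and sub-pixel values are
    allowed. Confidence is the pose estimator's per-frame certainty in [0, 1].
    """

    u: np.ndarray
    v: np.ndarray
    confidence: np.ndarray
    poi_names: tuple[str, ...] = POI_NAMES

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.confidence = np.asarray(self.confidence, dtype=float)
        n = len(self.poi_names)
        for name, arr in (("u", self.u), ("v", self.v), ("confidence", self.confidence)):
            if arr.ndim != 2 or arr.shape[1] != n:
                raise ValueError(f"{name} must have shape (n_frames, {n}), got {arr.shape}")
        if self.u.shape != self.v.shape or self.u.shape != self.confidence.shape:
            raise ValueError("u, v and confidence must share one shape")
        finite_conf = self.confidence[np.isfinite(self.confidence)]
        if finite_conf.size and (finite_conf.min() < 0 or finite_conf.max() > 1):
            raise ValueError("confidence values must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return int(self.u.shape[0])

    def poi_index(self, poi: str) -> int:
        try:
            return self.poi_names.index(poi)
        except ValueError:
            raise KeyError(f"unknown point of interest {poi!r}") from None


@dataclass
class DepthStack:
    """A sequence of depth frames in millimetres; 0 encodes the "black area".

    The black area is the depth-image region seen by only one of the two
    infrared sensors, where no range value exists.
    """

    frames: np.ndarray  # (n, H, W) unsigned integers, mm
    invalid_value: int = 0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be (n, H, W), got shape {self.frames.shape}")
        if np.issubdtype(self.frames.dtype, np.signedinteger) and self.frames.min() < 0:
            raise ValueError("depth values must be non-negative")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def height(self) -> int:
        return int(self.frames.shape[1])

    @property
    def width(self) -> int:
        return int(self.frames.shape[2])


@dataclass(frozen=True)
class CameraModel:
    """Pinhole intrinsics for the depth point of view plus stream resolutions.

    Axes follow the depth-camera convention: x right, y down, z forward along
    the optical axis; all 3D quantities are millimetres.
    """

    fx: float
    fy: float
    cx: float
    cy: float
    rgb_resolution: tuple[int, int] = (1280, 720)
    depth_resolution: tuple[int, int] = (640, 480)

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        w, h = self.depth_resolution
        if not (0 <= self.cx < w and 0 <= self.cy < h):
            raise ValueError("principal point must lie inside the depth image")


def default_camera() -> CameraModel:
    """A plausible wide-FOV depth camera (~58 deg horizontal) at 640x480."""
    return CameraModel(fx=580.0, fy=580.0, cx=319.5, cy=239.5)


# ---------------------------------------------------------------------------
# Pose-track CSV (DeepLabCut dialect)
# ---------------------------------------------------------------------------


def read_pose_csv(path: str | Path) -> Pose2DTrack:
    """Read a pose-track CSV with scorer / bodyparts / coords header rows.

    The bodyparts row must list exactly the six canonical points of interest
    (any order); the returned track is in canonical order. Likelihood is
    mapped to confidence unchanged.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if len(rows) < 4:
        raise FormatError(f"{path}: expected 3 header rows plus data")
    header_labels = [r[0].strip().lower() for r in rows[:3]]
    if header_labels != ["scorer", "bodyparts", "coords"]:
        bad = next(
            i for i, (got, want) in enumerate(zip(header_labels, ["scorer", "bodyparts", "coords"]))
            if got != want
        )
        raise FormatError(f"{path}: header row {bad + 1} should start with "
                          f"{['scorer', 'bodyparts', 'coords'][bad]!r}, got {rows[bad][0]!r}")
    bodyparts_row = rows[1][1:]
    coords_row = rows[2][1:]
    n_cols = len(bodyparts_row)
    if n_cols % 3 != 0 or len(coords_row) != n_cols:
        raise FormatError(f"{path}: bodyparts/coords rows must hold x,y,likelihood triplets")
    parts: list[str] = []
    for j in range(0, n_cols, 3):
        if [c.strip() for c in coords_row[j:j + 3]] != ["x", "y", "likelihood"]:
            raise FormatError(f"{path}: coords row columns {j + 1}..{j + 3} must be x,y,likelihood")
        triplet = {bodyparts_row[j + k].strip() for k in range(3)}
        if len(triplet) != 1:
            raise FormatError(f"{path}: bodyparts row inconsistent at columns {j + 1}..{j + 3}")
        parts.append(triplet.pop())
    missing = [p for p in POI_NAMES if p not in parts]
    if missing:
        raise FormatError(f"{path}: bodyparts row is missing PoI(s): {', '.join(missing)}")
    unknown = [p for p in parts if p not in POI_NAMES]
    if unknown:
        raise FormatError(f"{path}: unknown bodypart(s): {', '.join(unknown)}")

    data_rows = rows[3:]
    n_frames = len(data_rows)
    u = np.empty((n_frames, len(POI_NAMES)))
    v = np.empty_like(u)
    conf = np.empty_like(u)
    col_of = {p: 1 + 3 * i for i, p in enumerate(parts)}
    for fi, row in enumerate(data_rows):
        for pi, poi in enumerate(POI_NAMES):
            j = col_of[poi]
            try:
                u[fi, pi] = float(row[j])
                v[fi, pi] = float(row[j + 1])
                conf[fi, pi] = float(row[j + 2])
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}: non-numeric or missing cell at frame {fi}, "
                                  f"bodypart {poi}") from exc
    return Pose2DTrack(u=u, v=v, confidence=conf)


def write_pose_csv(track: Pose2DTrack, path: str | Path, scorer: str = "gm3d") -> None:
    """Write a pose track in the same dialect :func:`read_pose_csv` consumes."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["scorer"] + [scorer] * (3 * len(track.poi_names)))
        w.writerow(["bodyparts"] + [p for p in track.poi_names for _ in range(3)])
        w.writerow(["coords"] + ["x", "y", "likelihood"] * len(track.poi_names))
        for fi in range(track.n_frames):
            row: list[object] = [fi]
            for pi in range(len(track.poi_names)):
                row += [repr(float(track.u[fi, pi])), repr(float(track.v[fi, pi])),
                        repr(float(track.confidence[fi, pi]))]
            w.writerow(row)


# ---------------------------------------------------------------------------
# Depth stacks
# ---------------------------------------------------------------------------

_PNG_INDEX_RE = re.compile(r"(\d+)\.png$", re.IGNORECASE)


def read_depth_stack(dir_or_file: str | Path) -> DepthStack:
    """Read a depth stack from a PNG directory or a raw stack + text sidecar.

    PNG frames are 16-bit single-channel, named by frame index; indices must
    form a gapless 0..n-1 (or 1..n) sequence. A raw stack is ``<name>.raw``
    of little-endian uint16 with ``<name>.txt`` holding width/height/count.
    """
    p = Path(dir_or_file)
    if p.is_dir():
        entries = []
        for f in p.iterdir():
            m = _PNG_INDEX_RE.search(f.name)
            if m:
                entries.append((int(m.group(1)), f))
        if not entries:
            raise FormatError(f"{p}: no indexed .png frames found")
        entries.sort()
        indices = [i for i, _ in entries]
        base = indices[0]
        expected = list(range(base, base + len(indices)))
        if indices != expected:
            gaps = sorted(set(expected) - set(indices))
            raise FormatError(f"{p}: missing frame index(es): {gaps}")
        frames = []
        shape = None
        for idx, f in entries:
            img = np.asarray(iio.imread(f))
            if img.ndim != 2:
                raise FormatError(f"{f}: depth frames must be single-channel")
            if shape is None:
                shape = img.shape
            elif img.shape != shape:
                raise FormatError(f"{f}: frame dimensions {img.shape} differ from {shape}")
            frames.append(img.astype(np.uint16, copy=False))
        return DepthStack(frames=np.stack(frames))
    if p.suffix == ".raw" or (p.suffix == "" and p.with_suffix(".raw").exists()):
        raw = p if p.suffix == ".raw" else p.with_suffix(".raw")
        sidecar = raw.with_suffix(".txt")
        if not sidecar.exists():
            raise FormatError(f"{raw}: missing sidecar {sidecar.name}")
        meta: dict[str, int] = {}
        for line in sidecar.read_text().splitlines():
            if "=" in line:
                k, _, val = line.partition("=")
                meta[k.strip()] = int(val)
        try:
            w, h, n = meta["width"], meta["height"], meta["count"]
        except KeyError as exc:
            raise FormatError(f"{sidecar}: sidecar must define width, height, count") from exc
        data = np.fromfile(raw, dtype="<u2")
        if data.size != n * h * w:
            raise FormatError(f"{raw}: expected {n * h * w} values, found {data.size}")
        return DepthStack(frames=data.reshape(n, h, w))
    raise FormatError(f"{p}: not a directory of PNGs nor a .raw stack")


def write_depth_stack(stack: DepthStack, dir_or_file: str | Path,
                      fmt: str = "png") -> None:
    """Write a depth stack as a PNG sequence (``fmt='png'``) or raw stack."""
    p = Path(dir_or_file)
    frames = stack.frames.astype(np.uint16, copy=False)
    if fmt == "png":
        p.mkdir(parents=True, exist_ok=True)
        width = len(str(max(stack.n_frames - 1, 0)))
        for i in range(stack.n_frames):
            iio.imwrite(p / f"{i:0{max(width, 6)}d}.png", frames[i])
    elif fmt == "raw":
        raw = p if p.suffix == ".raw" else p.with_suffix(".raw")
        raw.parent.mkdir(parents=True, exist_ok=True)
        frames.astype("<u2").tofile(raw)
        raw.with_suffix(".txt").write_text(
            f"width = {stack.width}\nheight = {stack.height}\ncount = {stack.n_frames}\n"
        )
    else:
        raise ValueError(f"unknown depth format {fmt!r}")


# ---------------------------------------------------------------------------
# Timestamp logs
# ---------------------------------------------------------------------------


def read_timestamps_csv(path: str | Path, stream_id: str,
                        nominal_dt_ms: float = NOMINAL_DT_MS) -> TimestampSeries:
    """Read a two-column (frame_index, time_ms) timestamp log.

    Duplicated or decreasing timestamps are rejected: alignment assumes
    distinguishable frame times.
    """
    path = Path(path)
    times = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for i, row in enumerate(reader):
            if not row or (i == 0 and not _is_number(row[-1])):
                continue  # optional header
            if len(row) < 2:
                raise FormatError(f"{path}: row {i} needs frame_index, time_ms")
            try:
                times.append(float(row[1]))
            except ValueError as exc:
                raise FormatError(f"{path}: non-numeric time at row {i}") from exc
    arr = np.asarray(times)
    if arr.size >= 2 and not np.all(np.diff(arr) > 0):
        bad = int(np.flatnonzero(np.diff(arr) <= 0)[0]) + 1
        raise FormatError(f"{path}: timestamps not strictly increasing at frame {bad}")
    return TimestampSeries(stream_id=stream_id, times_ms=arr, nominal_dt_ms=nominal_dt_ms)


def write_timestamps_csv(ts: TimestampSeries, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["frame_index", "time_ms"])
        for i, t in enumerate(ts.times_ms):
            w.writerow([i, repr(float(t))])


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# Metrics report
# ---------------------------------------------------------------------------


def write_metrics_report(metrics, path: str | Path) -> tuple[Path, Path]:
    """Write a metric set as structured JSON plus a flat one-row CSV.

    ``path`` is used as a stem: ``<stem>.json`` and ``<stem>.csv`` are
    written. Metrics that could not be computed are written as explicit
    nulls, never silently dropped. Returns the two paths.
    """
    stem = Path(path)
    if stem.suffix in (".json", ".csv"):
        stem = stem.with_suffix("")
    payload = metrics.to_dict()
    json_path = stem.with_suffix(".json")
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    flat: dict[str, object] = {}
    for side in ("left", "right", "combined"):
        for key, val in payload["metrics"][side].items():
            flat[f"{key}_{side}"] = "" if val is None else repr(val)
    for side in ("left", "right"):
        bouts = payload["bouts"][side]
        for key in ("n_bouts", "mean_duration_s", "sd_duration_s", "movement_pct",
                    "speed_threshold_mm_s"):
            val = None if bouts is None else bouts[key]
            flat[f"bout_{key}_{side}"] = "" if val is None else repr(val)
    csv_path = stem.with_suffix(".csv")
    with open(csv_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(list(flat))
        w.writerow([flat[k] for k in flat])
    return json_path, csv_path


def read_metrics_report(path: str | Path):
    """Read back the JSON half of a metrics report."""
    from gm3d.gm_metrics import GMMetricSet

    stem = Path(path)
    if stem.suffix != ".json":
        stem = stem.with_suffix(".json")
    return GMMetricSet.from_dict(json.loads(stem.read_text()))
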