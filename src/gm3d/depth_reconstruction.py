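"""From aligned 2D tracks plus depth maps to artifact-cleaned 3D trajectories.

Three mechanisms corrupt the depth coordinate of a tracked point and each
gets a countermeasure, applied in a fixed order per point of interest:

1. the tracked pixel falls on the "black area" of the depth image (no range
   value) -> the sample is dropped (``black_area``);
2. the point is occluded in the RGB view, so the 2D estimate lands on the
   occluding surface and the sampled depth is biased; the pose estimator's
   confidence drops in exactly these frames, so samples with confidence
   below the threshold are dropped (``low_confidence``);
3. residual RGB/depth spatial misalignment near a depth discontinuity
   produces single-frame range spikes -> the first derivative of the depth
   coordinate is screened against a physical speed bound and the offending
   sample is dropped (``depth_jump``).

Interior runs of dropped samples are then refilled by cubic-spline
interpolation (u, v and z independently) and the completed pixel+depth
samples are back-projected through the pinhole model into camera-frame
millimetres (x right, y down, z forward).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from gm3d.formats_io import CameraModel, DepthStack, Pose2DTrack, POI_NAMES
from gm3d.stream_sync import AlignmentResult, GappedSeries, fill_gaps_spline

__all__ = [
    "ReconstructionParams", "Trajectory3D", "REASONS",
    "map_rgb_to_depth_pixel", "sample_depth", "gate_confidence",
    "despike_depth", "backproject", "reconstruct_trajectories", "BLACK",
]

#: Returned by :func:`sample_depth` when no valid depth exists in the patch.
BLACK = 0.0

#: Validity reason codes, in the order countermeasures are applied.
REASONS = ("ok", "alignment_gap", "low_confidence", "black_area",
           "depth_jump", "edge_unfilled")
_REASON_CODE = {name: i for i, name in enumerate(REASONS)}


@dataclass(frozen=True)
class ReconstructionParams:
    """Tunable thresholds of the cleaning chain.

    confidence_min:
        Pose-estimation confidence below which a frame is not considered
        (strict ``<``; default 0.6).
    max_subject_speed_mm_s:
        Physical bound on how fast the subject can move; depth-coordinate
        derivatives above it are treated as sensor artifacts. The default
        2000 mm/s is a generous bound for infant hand speed.
    depth_patch_radius_px:
        Half-width of the square patch whose valid-pixel median gives the
        sampled depth (default 1, i.e. 3x3).
    min_valid_fraction:
        Below this fraction of valid samples a warning is recorded in the
        QC counts.
    """

    confidence_min: float = 0.6
    max_subject_speed_mm_s: float = 2000.0
    depth_patch_radius_px: int = 1
    min_valid_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence_min <= 1.0:
            raise ValueError("confidence_min must be in [0, 1]")
        if self.max_subject_speed_mm_s <= 0:
            raise ValueError("max_subject_speed_mm_s must be positive")
        if self.depth_patch_radius_px < 0:
            raise ValueError("depth_patch_radius_px must be >= 0")


@dataclass
class Trajectory3D:
    """Cleaned camera-frame trajectories for all points of interest.

    ``xyz`` is ``(n_slots, n_poi, 3)`` in millimetres; NaN where no valid
    sample exists. ``reason`` holds, per slot and PoI, why the raw sample
    was discarded (``"ok"`` when the measurement survived); ``filled`` marks
    slots whose value was produced by spline interpolation. A slot is
    usable iff its reason is ``"ok"`` or it was filled. ``usable`` flags
    PoIs with enough support to be reconstructed at all.
    """

    xyz: np.ndarray
    slot_times_ms: np.ndarray
    reason: np.ndarray  # (n_slots, n_poi) small ints indexing REASONS
    filled: np.ndarray  # (n_slots, n_poi) bool
    usable: np.ndarray  # (n_poi,) bool
    poi_names: tuple[str, ...] = POI_NAMES
    removal_counts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def poi_index(self, poi: str) -> int:
        return self.poi_names.index(poi)

    def valid_mask(self, poi: str | int | None = None) -> np.ndarray:
        """Slots carrying a value (measured or filled)."""
        ok = (self.reason == _REASON_CODE["ok"]) | self.filled
        if poi is None:
            return ok
        idx = poi if isinstance(poi, int) else self.poi_index(poi)
        return ok[:, idx]

    def reason_names(self, poi: str | int) -> np.ndarray:
        idx = poi if isinstance(poi, int) else self.poi_index(poi)
        return np.asarray(REASONS, dtype=object)[self.reason[:, idx]]


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def map_rgb_to_depth_pixel(u_rgb: float, v_rgb: float,
                           camera: CameraModel) -> tuple[float, float, bool]:
    """Rescale an RGB pixel coordinate to the depth image.

    The two streams are factory pre-registered, so the mapping is a
    proportional rescaling (no lens-distortion model). Returns
    ``(u_d, v_d, clamped)``; out-of-bounds results are clamped to the image
    border and flagged.
    """
    wr, hr = camera.rgb_resolution
    wd, hd = camera.depth_resolution
    u_d = u_rgb * wd / wr
    v_d = v_rgb * hd / hr
    clamped = False
    if not (0 <= u_d <= wd - 1):
        u_d = min(max(u_d, 0.0), float(wd - 1))
        clamped = True
    if not (0 <= v_d <= hd - 1):
        v_d = min(max(v_d, 0.0), float(hd - 1))
        clamped = True
    return u_d, v_d, clamped


def sample_depth(frame: np.ndarray, u_d: float, v_d: float,
                 patch_radius: int = 1) -> float:
    """Median of the valid (nonzero) depths in a patch around the pixel.

    The patch is the ``(2r+1)**2`` square centred on the rounded pixel,
    cropped at the image border. Returns :data:`BLACK` (0.0) when every
    pixel in the patch lies in the black area.
    """
    h, w = frame.shape
    uc = int(round(u_d))
    vc = int(round(v_d))
    if not (0 <= uc < w and 0 <= vc < h):
        raise ValueError(f"pixel ({u_d}, {v_d}) outside {w}x{h} frame")
    r = patch_radius
    patch = frame[max(vc - r, 0):vc + r + 1, max(uc - r, 0):uc + r + 1]
    valid = patch[patch > 0]
    if valid.size == 0:
        return BLACK
    return float(np.median(valid))


def gate_confidence(track: Pose2DTrack, poi: str | int,
                    confidence_min: float = 0.6) -> np.ndarray:
    """Boolean mask of frames whose confidence is below the threshold.

    True marks an *invalid* frame (confidence strictly lower than
    ``confidence_min``); NaN confidence is treated as invalid.
    """
    idx = poi if isinstance(poi, int) else track.poi_index(poi)
    conf = track.confidence[:, idx]
    return ~(conf >= confidence_min)


def despike_depth(depth_series: np.ndarray, slot_times_ms: np.ndarray,
                  max_subject_speed_mm_s: float = 2000.0,
                  valid: np.ndarray | None = None) -> np.ndarray:
    """Causal screening of the depth coordinate against a speed bound.

    Walks the valid samples once in time order; each candidate is compared
    against the last *surviving* sample, and removed when
    ``|dz| / dt`` exceeds the bound (the later sample of the jump is always
    the one removed). Because comparison restarts from the survivor, a
    genuine level change lasting several frames does not cascade into mass
    deletion: only its first, too-fast frame pair loses one sample per
    pass-through until a surviving sample confirms the new level.

    Returns a boolean mask, True where the sample was removed.
    """
    z = np.asarray(depth_series, dtype=float)
    t = np.asarray(slot_times_ms, dtype=float)
    if valid is None:
        valid = np.isfinite(z)
    idx = np.flatnonzero(valid)
    if idx.size < 2:
        return np.zeros_like(z, dtype=bool)
    if not np.all(np.diff(t[idx]) > 0):
        raise ValueError("slot times must be strictly increasing")
    removed = np.zeros_like(z, dtype=bool)
    last = idx[0]
    n_kept = 1
    for k in idx[1:]:
        dt_s = (t[k] - t[last]) / 1000.0
        rate = abs(z[k] - z[last]) / dt_s
        if rate > max_subject_speed_mm_s:
            removed[k] = True
        else:
            last = k
            n_kept += 1
    if n_kept < 2:
        frac = removed.sum() / idx.size
        raise ValueError(f"despiking removed {frac:.0%} of samples; "
                         "series is unusable")
    return removed


def backproject(u_d: float, v_d: float, depth_mm: float,
                camera: CameraModel) -> tuple[float, float, float]:
    """Invert the pinhole projection: pixel + range -> camera-frame mm."""
    if not depth_mm > 0:
        raise ValueError(f"depth must be positive, got {depth_mm}")
    z = float(depth_mm)
    x = (u_d - camera.cx) * z / camera.fx
    y = (v_d - camera.cy) * z / camera.fy
    return x, y, z


def project(x: float, y: float, z: float,
            camera: CameraModel) -> tuple[float, float]:
    """Forward pinhole projection onto the depth image plane."""
    if not z > 0:
        raise ValueError("point must lie in front of the camera")
    return camera.cx + x * camera.fx / z, camera.cy + y * camera.fy / z


# ---------------------------------------------------------------------------
# Full reconstruction
# ---------------------------------------------------------------------------


def reconstruct_trajectories(track: Pose2DTrack, depth: DepthStack,
                             align: AlignmentResult, camera: CameraModel,
                             params: ReconstructionParams | None = None,
                             ) -> Trajectory3D:
    """Run the full cleaning chain for every point of interest.

    Per PoI and slot, in order: alignment slotting (a slot missing either
    stream is an ``alignment_gap``), confidence gating, black-area depth
    sampling, derivative despiking, cubic-spline filling of interior
    invalid runs in u, v and z independently, pinhole back-projection.

    Every output sample is exactly one of: untouched measurement
    (reason ``ok``, not filled), spline-filled, or flagged invalid;
    ``removal_counts`` reports the partition per PoI.
    """
    if params is None:
        params = ReconstructionParams()
    if track.n_frames != int((align.rgb_index >= 0).sum()):
        raise ValueError("pose track frame count does not match RGB frames in alignment")
    if depth.n_frames != int((align.depth_index >= 0).sum()):
        raise ValueError("depth stack frame count does not match depth frames in alignment")

    n_slots = align.n_slots
    n_poi = len(track.poi_names)
    t = align.slot_times_ms
    xyz = np.full((n_slots, n_poi, 3), np.nan)
    reason = np.zeros((n_slots, n_poi), dtype=np.int8)
    filled = np.zeros((n_slots, n_poi), dtype=bool)
    usable = np.ones(n_poi, dtype=bool)
    counts: dict[str, dict[str, int]] = {}
    warnings: list[str] = []

    slot_has_both = (align.rgb_index >= 0) & (align.depth_index >= 0)

    for pi, poi in enumerate(track.poi_names):
        u = np.full(n_slots, np.nan)
        v = np.full(n_slots, np.nan)
        z = np.full(n_slots, np.nan)
        poi_reason = np.zeros(n_slots, dtype=np.int8)

        # alignment slotting
        poi_reason[~slot_has_both] = _REASON_CODE["alignment_gap"]

        low_conf = gate_confidence(track, pi, params.confidence_min)
        for s in range(n_slots):
            if not slot_has_both[s]:
                continue
            ri = align.rgb_index[s]
            di = align.depth_index[s]
            if low_conf[ri]:
                poi_reason[s] = _REASON_CODE["low_confidence"]
                continue
            u_d, v_d, _ = map_rgb_to_depth_pixel(track.u[ri, pi], track.v[ri, pi], camera)
            d = sample_depth(depth.frames[di], u_d, v_d, params.depth_patch_radius_px)
            if d == BLACK:
                poi_reason[s] = _REASON_CODE["black_area"]
                continue
            u[s], v[s], z[s] = u_d, v_d, d

        ok = poi_reason == _REASON_CODE["ok"]
        if ok.sum() >= 2:
            spiked = despike_depth(z, t, params.max_subject_speed_mm_s, valid=ok)
            poi_reason[spiked] = _REASON_CODE["depth_jump"]
            u[spiked] = v[spiked] = z[spiked] = np.nan
            ok = poi_reason == _REASON_CODE["ok"]

        n_ok = int(ok.sum())
        if n_ok < 4:
            usable[pi] = False
            warnings.append(f"{poi}: only {n_ok} valid samples; trajectory unusable")
            counts[poi] = _tally(poi_reason, filled[:, pi])
            reason[:, pi] = poi_reason
            continue
        if n_ok < params.min_valid_fraction * n_slots:
            warnings.append(
                f"{poi}: only {n_ok}/{n_slots} samples valid before gap filling")

        # spline-fill interior invalid runs in u, v, z independently
        for arr in (u, v, z):
            arr[~ok] = np.nan
        fu = fill_gaps_spline(GappedSeries(u, t))
        fv = fill_gaps_spline(GappedSeries(v, t))
        fz = fill_gaps_spline(GappedSeries(z, t))
        poi_filled = fu.filled_mask.copy()
        edge = fu.edge_unfilled
        poi_reason[edge & (poi_reason == _REASON_CODE["ok"])] = _REASON_CODE["edge_unfilled"]

        value_ok = ok | poi_filled
        for s in np.flatnonzero(value_ok):
            zz = fz.values[s]
            if zz > 0:
                xyz[s, pi] = backproject(fu.values[s], fv.values[s], zz, camera)
            else:
                value_ok[s] = False
                poi_filled[s] = False

        filled[:, pi] = poi_filled
        reason[:, pi] = poi_reason
        counts[poi] = _tally(poi_reason, poi_filled)

    return Trajectory3D(xyz=xyz, slot_times_ms=t.copy(), reason=reason,
                        filled=filled, usable=usable,
                        poi_names=track.poi_names,
                        removal_counts=counts, warnings=warnings)


def _tally(poi_reason: np.ndarray, poi_filled: np.ndarray) -> dict[str, int]:
    out = {name: int((poi_reason == code).sum())
           for name, code in _REASON_CODE.items()}
    out["filled"] = int(poi_filled.sum())
    out["untouched"] = out.pop("ok")
    return out


def write_reconstruction_qc(traj: Trajectory3D, path) -> None:
    """Per-slot, per-PoI QC table: coordinates, validity reason, fill flag."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["slot", "poi", "x_mm", "y_mm", "z_mm", "reason", "filled"])
        for pi, poi in enumerate(traj.poi_names):
            names = traj.reason_names(pi)
            for s in range(traj.xyz.shape[0]):
                x, y, z = traj.xyz[s, pi]
                w.writerow([s, poi,
                            "" if np.isnan(x) else repr(float(x)),
                            "" if np.isnan(y) else repr(float(y)),
                            "" if np.isnan(z) else repr(float(z)),
                            names[s], int(traj.filled[s, pi])])
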