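"""Seeded generator of complete synthetic RGB-D recordings with ground truth.

A recording consists of the four observables the pipeline consumes — two
timestamp logs, a 2D pose track with confidence, and a depth stack — plus a
:class:`GroundTruth` object holding the latent kinematics and the exact
location of every injected artifact, so each pipeline stage can be tested
against known answers without any real data.

The motion model is a sum of sinusoids per point of interest and axis
(slow voluntary components plus a faster low-amplitude tremor band) around
an infant-scale supine base pose, optionally gated by a smooth
activity envelope to create quiescent intervals. Left/right pairs share a
common sinusoid set with weight ``sqrt(rho)`` (mirrored in x) against
independent sets with weight ``sqrt(1-rho)``, so the bilateral coupling of
the two arms is a single dial. Because the latent trajectory is an explicit
function of time, ground truth is available at any timestamp.

Sensor artifacts are injected exactly as the depth countermeasures expect
them: "black area" discs (depth zeroed around the point), occlusions
(depth biased towards the camera-facing surface with confidence dropped
below the gate in the same frames), and single-frame depth spikes standing
in for residual RGB/depth misalignment at depth discontinuities. Both
frame clocks carry Gaussian timestamp jitter and may drop frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
import json

import numpy as np

from gm3d.formats_io import (
    CameraModel, DepthStack, Pose2DTrack, TimestampSeries, POI_NAMES,
    default_camera, write_depth_stack, write_pose_csv, write_timestamps_csv,
)
from gm3d.gm_metrics import BoutSet, detect_bouts

__all__ = ["ScenarioSpec", "GroundTruth", "Recording", "LatentKinematics",
           "generate_recording", "preset_cohort", "write_recording"]

_PAIRS = (("LS", "RS"), ("LE", "RE"), ("LW", "RW"))

#: Supine infant base pose in the depth-camera frame, mm.
_BASE_POSE = {
    "LS": (-60.0, -50.0, 900.0), "RS": (60.0, -50.0, 900.0),
    "LE": (-130.0, 10.0, 890.0), "RE": (130.0, 10.0, 890.0),
    "LW": (-170.0, 90.0, 870.0), "RW": (170.0, 90.0, 870.0),
}


@dataclass(frozen=True)
class ScenarioSpec:
    """Full parameterisation of one synthetic recording.

    The defaults describe a plausible 30 s supine recording at ~30 fps with
    mild clock jitter, a few percent of dropped frames, and artifact rates
    of a few percent per mechanism. ``seed`` fully determines the output.
    """

    duration_s: float = 30.0
    rate_rgb_hz: float = 30.0
    rate_depth_hz: float = 30.0
    timestamp_jitter_ms_sd: float = 2.0
    depth_clock_offset_ms: float | None = None  # None -> drawn U(-5, 5)
    drop_rate_rgb: float = 0.02
    drop_rate_depth: float = 0.02

    n_motion_components: int = 3
    freq_range_hz: tuple[float, float] = (0.3, 2.0)
    wrist_amp_mm: tuple[float, float, float] = (40.0, 40.0, 15.0)
    elbow_amp_mm: tuple[float, float, float] = (20.0, 20.0, 8.0)
    shoulder_amp_mm: tuple[float, float, float] = (6.0, 6.0, 3.0)
    n_tremor_components: int = 4
    tremor_sd_mm: float = 1.5
    tremor_freq_range_hz: tuple[float, float] = (3.0, 8.0)
    bilateral_coupling: float = 0.0
    quiet_fraction: float = 0.0

    black_area_rate: float = 0.05
    low_confidence_rate: float = 0.05
    occlusion_bias_mm: float = 150.0
    misalignment_spike_rate: float = 0.003
    misalignment_spike_mm: float = 400.0
    misalignment_spikes_per_poi: int | None = None

    disc_radius_px: int = 9
    background_depth_mm: int = 1400
    camera: CameraModel = field(default_factory=default_camera)
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.duration_s <= 0:
            problems.append("duration_s must be positive")
        for name in ("drop_rate_rgb", "drop_rate_depth"):
            v = getattr(self, name)
            if not 0 <= v <= 0.2:
                problems.append(f"{name} must be in [0, 0.2]")
        for name in ("black_area_rate", "low_confidence_rate",
                     "misalignment_spike_rate", "quiet_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                problems.append(f"{name} must be in [0, 1]")
        if not -1 <= self.bilateral_coupling <= 1:
            problems.append("bilateral_coupling must be in [-1, 1]")
        nyq = min(self.rate_rgb_hz, self.rate_depth_hz) / 2
        for name in ("freq_range_hz", "tremor_freq_range_hz"):
            lo, hi = getattr(self, name)
            if not 0 < lo < hi:
                problems.append(f"{name} must be an increasing positive pair")
            elif hi >= nyq:
                problems.append(f"{name} upper bound must stay below the "
                                f"Nyquist rate {nyq} Hz")
        if problems:
            raise ValueError("invalid scenario: " + "; ".join(problems))


class LatentKinematics:
    """Evaluable ground-truth kinematics: base pose + sinusoid bank + envelope."""

    def __init__(self, base: np.ndarray, amp: np.ndarray, freq: np.ndarray,
                 phase: np.ndarray, bumps: list[tuple[float, float]] | None,
                 ramp_s: float = 0.5):
        self.base = base          # (6, 3)
        self.amp = amp            # (6, 3, K)
        self.freq = freq          # (6, 3, K) Hz
        self.phase = phase        # (6, 3, K) rad
        self.bumps = bumps        # activity windows (center_s, half_width_s)
        self.ramp_s = ramp_s

    def envelope(self, t_s: np.ndarray) -> np.ndarray:
        if self.bumps is None:
            return np.ones_like(t_s)
        env = np.zeros_like(t_s, dtype=float)
        for c, hw in self.bumps:
            d = np.abs(t_s - c)
            core = d <= hw
            ramp = (d > hw) & (d < hw + self.ramp_s)
            bump = np.zeros_like(env)
            bump[core] = 1.0
            bump[ramp] = 0.5 * (1 + np.cos(np.pi * (d[ramp] - hw) / self.ramp_s))
            env = np.maximum(env, bump)
        return env

    def positions_at(self, times_ms: np.ndarray) -> np.ndarray:
        """Latent (n_t, 6, 3) positions in mm at the given times."""
        t = np.atleast_1d(np.asarray(times_ms, dtype=float)) / 1000.0
        arg = 2 * np.pi * self.freq[None] * t[:, None, None, None] + self.phase[None]
        dev = (self.amp[None] * np.sin(arg)).sum(axis=-1)
        dev *= self.envelope(t)[:, None, None]
        return self.base[None] + dev

    def velocities_at(self, times_ms: np.ndarray,
                      h_ms: float = 5.0) -> np.ndarray:
        """Central-difference latent velocities, mm/s."""
        t = np.atleast_1d(np.asarray(times_ms, dtype=float))
        return (self.positions_at(t + h_ms) - self.positions_at(t - h_ms)) \
            / (2 * h_ms / 1000.0)

    def to_dict(self) -> dict:
        return {
            "base": self.base.tolist(), "amp": self.amp.tolist(),
            "freq": self.freq.tolist(), "phase": self.phase.tolist(),
            "bumps": self.bumps, "ramp_s": self.ramp_s,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LatentKinematics":
        bumps = None if d["bumps"] is None else [tuple(b) for b in d["bumps"]]
        return cls(np.asarray(d["base"]), np.asarray(d["amp"]),
                   np.asarray(d["freq"]), np.asarray(d["phase"]),
                   bumps, d["ramp_s"])


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    latent: LatentKinematics
    black_area: dict      # poi -> depth-frame indices (post-drop numbering)
    low_confidence: dict  # poi -> rgb-frame indices
    depth_spikes: dict    # poi -> depth-frame indices
    spike_signs: dict     # poi -> +-1 per spike
    dropped_rgb: np.ndarray
    dropped_depth: np.ndarray
    true_bouts: dict      # side -> BoutSet on a dense uniform clock
    camera: CameraModel

    def elbow_angles_at(self, times_ms: np.ndarray) -> dict[str, np.ndarray]:
        """True elbow angles (degrees) per side at the given times."""
        pos = self.latent.positions_at(times_ms)
        out = {}
        for side, (s, e, w) in (("left", ("LS", "LE", "LW")),
                                ("right", ("RS", "RE", "RW"))):
            idx = [POI_NAMES.index(p) for p in (s, e, w)]
            ua = pos[:, idx[0]] - pos[:, idx[1]]
            fa = pos[:, idx[2]] - pos[:, idx[1]]
            cosang = np.einsum("ij,ij->i", ua, fa) / (
                np.linalg.norm(ua, axis=1) * np.linalg.norm(fa, axis=1))
            out[side] = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
        return out

    def to_json(self) -> str:
        return json.dumps({
            "latent": self.latent.to_dict(),
            "black_area": {k: np.asarray(v).tolist() for k, v in self.black_area.items()},
            "low_confidence": {k: np.asarray(v).tolist() for k, v in self.low_confidence.items()},
            "depth_spikes": {k: np.asarray(v).tolist() for k, v in self.depth_spikes.items()},
            "spike_signs": {k: np.asarray(v).tolist() for k, v in self.spike_signs.items()},
            "dropped_rgb": self.dropped_rgb.tolist(),
            "dropped_depth": self.dropped_depth.tolist(),
            "true_bouts": {s: (b.to_dict() if b else None)
                           for s, b in self.true_bouts.items()},
            "camera": asdict(self.camera),
        }, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        cam = d["camera"]
        cam["rgb_resolution"] = tuple(cam["rgb_resolution"])
        cam["depth_resolution"] = tuple(cam["depth_resolution"])
        return cls(
            latent=LatentKinematics.from_dict(d["latent"]),
            black_area={k: np.asarray(v, dtype=int) for k, v in d["black_area"].items()},
            low_confidence={k: np.asarray(v, dtype=int) for k, v in d["low_confidence"].items()},
            depth_spikes={k: np.asarray(v, dtype=int) for k, v in d["depth_spikes"].items()},
            spike_signs={k: np.asarray(v, dtype=float) for k, v in d["spike_signs"].items()},
            dropped_rgb=np.asarray(d["dropped_rgb"], dtype=int),
            dropped_depth=np.asarray(d["dropped_depth"], dtype=int),
            true_bouts={s: (BoutSet.from_dict(b) if b else None)
                        for s, b in d["true_bouts"].items()},
            camera=CameraModel(**cam),
        )


@dataclass
class Recording:
    """One synthetic recording: the four observables plus ground truth."""

    rgb_ts: TimestampSeries
    depth_ts: TimestampSeries
    track: Pose2DTrack
    depth: DepthStack
    ground_truth: GroundTruth
    spec: ScenarioSpec


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _sinusoid_bank(rng: np.random.Generator, spec: ScenarioSpec) -> LatentKinematics:
    """Draw the sinusoid components, applying bilateral coupling per pair."""
    K = spec.n_motion_components + spec.n_tremor_components
    amp = np.zeros((6, 3, 2 * K))
    freq = np.zeros_like(amp)
    phase = np.zeros_like(amp)
    base = np.array([_BASE_POSE[p] for p in POI_NAMES])
    amp_of = {"S": spec.shoulder_amp_mm, "E": spec.elbow_amp_mm,
              "W": spec.wrist_amp_mm}
    rho = spec.bilateral_coupling
    w_common = np.sqrt(abs(rho))
    w_own = np.sqrt(1 - abs(rho))
    sign_common = 1.0 if rho >= 0 else -1.0

    def draw_set(axis_amp: tuple[float, float, float]) -> tuple[np.ndarray, ...]:
        a = np.zeros((3, K))
        f = np.zeros((3, K))
        ph = rng.uniform(0, 2 * np.pi, size=(3, K))
        nm, nt = spec.n_motion_components, spec.n_tremor_components
        for ax in range(3):
            w = rng.uniform(0.5, 1.0, nm)
            a[ax, :nm] = axis_amp[ax] * w / w.sum()
            a[ax, nm:] = spec.tremor_sd_mm * np.sqrt(2.0 / max(nt, 1))
            f[ax, :nm] = rng.uniform(*spec.freq_range_hz, nm)
            f[ax, nm:] = rng.uniform(*spec.tremor_freq_range_hz, nt)
        return a, f, ph

    for left, right in _PAIRS:
        li = POI_NAMES.index(left)
        ri = POI_NAMES.index(right)
        a_c, f_c, p_c = draw_set(amp_of[left[1]])
        a_l, f_l, p_l = draw_set(amp_of[left[1]])
        a_r, f_r, p_r = draw_set(amp_of[left[1]])
        amp[li, :, :K] = w_common * a_c
        freq[li, :, :K] = f_c
        phase[li, :, :K] = p_c
        amp[li, :, K:] = w_own * a_l
        freq[li, :, K:] = f_l
        phase[li, :, K:] = p_l
        # the common drive is mirrored in x on the right side
        a_cr = a_c.copy()
        a_cr[0] *= -1.0
        amp[ri, :, :K] = sign_common * w_common * a_cr
        freq[ri, :, :K] = f_c
        phase[ri, :, :K] = p_c
        amp[ri, :, K:] = w_own * a_r
        freq[ri, :, K:] = f_r
        phase[ri, :, K:] = p_r

    bumps = None
    if spec.quiet_fraction > 0:
        bump_len = 3.0
        active = (1 - spec.quiet_fraction) * spec.duration_s
        n_bumps = max(1, int(round(active / bump_len)))
        centers = (np.arange(n_bumps) + 0.5) * spec.duration_s / n_bumps
        centers = centers + rng.uniform(-0.5, 0.5, n_bumps)
        bumps = [(float(c), bump_len / 2) for c in centers]
    return LatentKinematics(base, amp, freq, phase, bumps)


def _stream_times(rng: np.random.Generator, rate_hz: float, duration_s: float,
                  offset_ms: float, jitter_sd: float, drop_rate: float,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Jittered, decimated frame times; returns (times_ms, dropped_positions)."""
    dt = 1000.0 / rate_hz
    n = int(round(duration_s * rate_hz)) + 1
    jitter = rng.normal(0, jitter_sd, n) if jitter_sd > 0 else np.zeros(n)
    np.clip(jitter, -0.4 * dt, 0.4 * dt, out=jitter)
    times = offset_ms + dt * np.arange(n) + jitter
    keep = np.ones(n, dtype=bool)
    if drop_rate > 0:
        interior = np.arange(1, n - 1)
        n_drop = int(round(drop_rate * n))
        if n_drop:
            keep[rng.choice(interior, size=n_drop, replace=False)] = False
    return times[keep], np.flatnonzero(~keep)


def _project_px(pos: np.ndarray, cam: CameraModel) -> tuple[np.ndarray, np.ndarray]:
    """(n, 6, 3) mm -> depth-pixel (u, v) arrays of shape (n, 6)."""
    u = cam.cx + pos[..., 0] * cam.fx / pos[..., 2]
    v = cam.cy + pos[..., 1] * cam.fy / pos[..., 2]
    return u, v


def generate_recording(spec: ScenarioSpec) -> Recording:
    """Generate one complete synthetic recording from a scenario spec.

    Identical specs (including the seed) yield bit-identical outputs.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    latent = _sinusoid_bank(rng, spec)
    cam = spec.camera

    offset = spec.depth_clock_offset_ms
    if offset is None:
        offset = float(rng.uniform(-5.0, 5.0))
    rgb_times, dropped_rgb = _stream_times(
        rng, spec.rate_rgb_hz, spec.duration_s, 0.0,
        spec.timestamp_jitter_ms_sd, spec.drop_rate_rgb)
    depth_times, dropped_depth = _stream_times(
        rng, spec.rate_depth_hz, spec.duration_s, offset,
        spec.timestamp_jitter_ms_sd, spec.drop_rate_depth)
    n_rgb = rgb_times.size
    n_depth = depth_times.size

    # --- 2D track at RGB frame times -------------------------------------
    pos_rgb = latent.positions_at(rgb_times)           # (n_rgb, 6, 3)
    u_d, v_d = _project_px(pos_rgb, cam)
    wr, hr = cam.rgb_resolution
    wd, hd = cam.depth_resolution
    u_rgb = u_d * wr / wd
    v_rgb = v_d * hr / hd
    conf = rng.uniform(0.91, 0.99, size=(n_rgb, 6))

    # --- artifact frame selection ----------------------------------------
    # Low-confidence (occlusion) events live in RGB frame space; the depth
    # bias lands on the time-nearest depth frame so that the confidence gate
    # removes exactly the biased samples. Black areas and misalignment
    # spikes are depth-sensor artifacts and live in depth frame space,
    # kept clear of occlusion frames so each mechanism is attributable.
    margin = 10
    n_black = int(round(spec.black_area_rate * n_depth))
    n_lowc = int(round(spec.low_confidence_rate * n_rgb))
    if spec.misalignment_spikes_per_poi is not None:
        n_spike = spec.misalignment_spikes_per_poi
    else:
        n_spike = int(round(spec.misalignment_spike_rate * n_depth))
    black: dict[str, np.ndarray] = {}
    lowc: dict[str, np.ndarray] = {}
    spikes: dict[str, np.ndarray] = {}
    signs: dict[str, np.ndarray] = {}
    occluded_depth: dict[str, np.ndarray] = {}
    for pi, poi in enumerate(POI_NAMES):
        rgb_pool = rng.permutation(np.arange(margin, n_rgb - margin))
        lowc[poi] = np.sort(rgb_pool[:n_lowc])
        conf[lowc[poi], pi] = rng.uniform(0.05, 0.55, n_lowc)
        occ = _nearest_depth_frames(rgb_times[lowc[poi]], depth_times, rgb_times)
        occluded_depth[poi] = occ
        excluded = np.unique(np.concatenate([occ - 1, occ, occ + 1]))
        depth_pool = np.setdiff1d(np.arange(margin, n_depth - margin), excluded)
        depth_pool = rng.permutation(depth_pool)
        black[poi] = np.sort(depth_pool[:n_black])
        spikes[poi] = np.sort(depth_pool[n_black:n_black + n_spike])
        signs[poi] = rng.choice([-1.0, 1.0], size=spikes[poi].size)

    track = Pose2DTrack(u=u_rgb, v=v_rgb, confidence=conf)

    # --- depth stack at depth frame times ---------------------------------
    pos_depth = latent.positions_at(depth_times)       # (n_depth, 6, 3)
    ud_depth, vd_depth = _project_px(pos_depth, cam)
    frames = np.full((n_depth, hd, wd), spec.background_depth_mm, dtype=np.uint16)
    r = spec.disc_radius_px
    r_black = r + 3
    occ_set = {poi: set(ix.tolist()) for poi, ix in occluded_depth.items()}
    spike_map = {poi: {int(f): s for f, s in zip(ix, signs[poi])}
                 for poi, ix in spikes.items()}
    black_set = {poi: set(ix.tolist()) for poi, ix in black.items()}
    for i in range(n_depth):
        order = np.argsort(-pos_depth[i, :, 2])  # far PoIs first
        for pi in order:
            poi = POI_NAMES[pi]
            z = pos_depth[i, pi, 2]
            if i in occ_set[poi]:
                z = z + spec.occlusion_bias_mm
            if i in spike_map[poi]:
                z = z + spike_map[poi][i] * spec.misalignment_spike_mm
            _draw_disc(frames[i], ud_depth[i, pi], vd_depth[i, pi], r,
                       int(round(max(z, 1.0))))
        for pi in range(6):
            poi = POI_NAMES[pi]
            if i in black_set[poi]:
                _draw_disc(frames[i], ud_depth[i, pi], vd_depth[i, pi],
                           r_black, 0)
    depth = DepthStack(frames=frames)

    # --- ground-truth bouts on a dense uniform clock ----------------------
    dense = np.arange(0.0, spec.duration_s * 1000.0, 1000.0 / 30.0)
    vel = latent.velocities_at(dense)
    true_bouts = {}
    for side, wname in (("left", "LW"), ("right", "RW")):
        wi = POI_NAMES.index(wname)
        speed = np.linalg.norm(vel[:, wi, :], axis=1)
        true_bouts[side] = detect_bouts(speed, 30.0, 0.05)

    gt = GroundTruth(latent=latent, black_area=black, low_confidence=lowc,
                     depth_spikes=spikes, spike_signs=signs,
                     dropped_rgb=dropped_rgb, dropped_depth=dropped_depth,
                     true_bouts=true_bouts, camera=cam)
    return Recording(
        rgb_ts=TimestampSeries("rgb", rgb_times,
                               nominal_dt_ms=1000.0 / spec.rate_rgb_hz),
        depth_ts=TimestampSeries("depth", depth_times,
                                 nominal_dt_ms=1000.0 / spec.rate_depth_hz),
        track=track, depth=depth, ground_truth=gt, spec=spec)


def _nearest_depth_frames(rgb_times: np.ndarray, depth_times: np.ndarray,
                          all_rgb_times: np.ndarray | None = None,
                          tol_ms: float = 17.0) -> np.ndarray:
    """Depth frames time-paired with the given RGB frames.

    A depth frame qualifies when it is the nearest depth frame to the RGB
    frame, the RGB frame is in turn its nearest RGB frame, and the two are
    within the alignment tolerance — i.e. exactly the pairs the alignment
    stage will put in one slot. An occluded RGB frame whose depth partner
    was dropped simply has no depth counterpart to bias.
    """
    if rgb_times.size == 0:
        return np.asarray([], dtype=int)
    j = np.searchsorted(depth_times, rgb_times).clip(1, depth_times.size - 1)
    left_closer = (rgb_times - depth_times[j - 1]) <= (depth_times[j] - rgb_times)
    j = np.where(left_closer, j - 1, j)
    ok = np.abs(depth_times[j] - rgb_times) < tol_ms
    # mutuality: the depth frame's nearest RGB time must be this RGB time
    all_rgb = rgb_times if all_rgb_times is None else all_rgb_times
    k = np.searchsorted(all_rgb, depth_times[j]).clip(1, all_rgb.size - 1)
    left_closer_r = (depth_times[j] - all_rgb[k - 1]) <= (all_rgb[k] - depth_times[j])
    nearest_rgb = np.where(left_closer_r, all_rgb[k - 1], all_rgb[k])
    ok &= nearest_rgb == rgb_times
    return np.unique(j[ok])


def _draw_disc(frame: np.ndarray, u: float, v: float, radius: int,
               value: int) -> None:
    h, w = frame.shape
    uc, vc = int(round(u)), int(round(v))
    y0, y1 = max(vc - radius, 0), min(vc + radius + 1, h)
    x0, x1 = max(uc - radius, 0), min(uc + radius + 1, w)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.ogrid[y0:y1, x0:x1]
    mask = (yy - vc) ** 2 + (xx - uc) ** 2 <= radius ** 2
    frame[y0:y1, x0:x1][mask] = value


# ---------------------------------------------------------------------------
# Cohort presets
# ---------------------------------------------------------------------------

_PRESETS = {
    "coordinated": dict(bilateral_coupling=0.9),
    "chaotic": dict(bilateral_coupling=0.0, n_motion_components=6,
                    freq_range_hz=(0.2, 5.0)),
    "periodic": dict(n_motion_components=1, freq_range_hz=(0.6, 0.9),
                     tremor_sd_mm=0.5),
    "hypokinetic": dict(wrist_amp_mm=(8.0, 8.0, 3.0),
                        elbow_amp_mm=(4.0, 4.0, 1.6),
                        shoulder_amp_mm=(1.2, 1.2, 0.6),
                        tremor_sd_mm=0.3, quiet_fraction=0.6),
}


def preset_cohort(name: str, n: int, seed: int,
                  **overrides) -> list[Recording]:
    """Generate ``n`` recordings of a named behavioural cohort.

    ``coordinated``: strongly coupled arms; ``chaotic``: independent
    broadband motion; ``periodic``: a single dominant oscillation;
    ``hypokinetic``: 5x smaller amplitudes with long quiescent intervals.
    Seeds are ``seed + i`` for recording ``i``.
    """
    if name not in _PRESETS:
        raise ValueError(f"unknown cohort {name!r}; choose from "
                         f"{sorted(_PRESETS)}")
    if n < 1:
        raise ValueError("n must be >= 1")
    params = dict(_PRESETS[name])
    params.update(overrides)
    return [generate_recording(ScenarioSpec(seed=seed + i, **params))
            for i in range(n)]


# ---------------------------------------------------------------------------
# On-disk emission
# ---------------------------------------------------------------------------


def write_recording(rec: Recording, outdir: str | Path,
                    depth_format: str = "raw") -> dict[str, Path]:
    """Write a recording in exactly the external formats the readers expect.

    Emits the two timestamp CSVs, the pose CSV, the depth stack (raw by
    default, ``depth_format="png"`` for a PNG sequence), the ground-truth
    sidecar JSON and the scenario echo JSON. Returns the path map.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "rgb_timestamps": out / "rgb_timestamps.csv",
        "depth_timestamps": out / "depth_timestamps.csv",
        "pose": out / "pose.csv",
        "depth": out / ("depth" if depth_format == "png" else "depth.raw"),
        "ground_truth": out / "ground_truth.json",
        "scenario": out / "scenario.json",
    }
    write_timestamps_csv(rec.rgb_ts, paths["rgb_timestamps"])
    write_timestamps_csv(rec.depth_ts, paths["depth_timestamps"])
    write_pose_csv(rec.track, paths["pose"])
    write_depth_stack(rec.depth, paths["depth"], fmt=depth_format)
    paths["ground_truth"].write_text(rec.ground_truth.to_json() + "\n")
    spec_dict = asdict(rec.spec)
    spec_dict["camera"]["rgb_resolution"] = list(spec_dict["camera"]["rgb_resolution"])
    spec_dict["camera"]["depth_resolution"] = list(spec_dict["camera"]["depth_resolution"])
    paths["scenario"].write_text(json.dumps(spec_dict, indent=2, sort_keys=True) + "\n")
    return paths
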