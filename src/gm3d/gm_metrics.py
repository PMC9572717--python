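"""General-movement quantification metrics from cleaned 3D trajectories.

Nine metrics are computed per wrist/arm, following the GM quantification
literature: four "area" metrics comparing wrist trajectories and speed
profiles against their 2-s moving average and moving SD, two periodicity
metrics, the skewness of the wrist speed, the left/right cross-correlation
of wrist accelerations, and the range of motion (ROM) of the elbow angle.

To limit the influence of long quiescent intervals, activity bouts are
first detected as maximal runs where wrist speed exceeds 5% of its maximum,
and metric evaluation is restricted to bout samples (configurable).

All metrics operate on a uniformly resampled clock (default 30 Hz) because
the acquisition rate is only nominally constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import signal, stats
from scipy.interpolate import CubicSpline

from gm3d.depth_reconstruction import Trajectory3D

__all__ = [
    "MetricsConfig", "KinematicSeries", "BoutSet", "GMMetricSet",
    "resample_uniform", "differentiate", "moving_stats",
    "metric_dev_area", "metric_outside_sd_area", "metric_periodicity",
    "metric_skewness", "metric_accel_xcorr", "elbow_angle_series",
    "detect_bouts", "compute_all_metrics",
]

METRIC_KEYS = (
    "traj_dev_area", "traj_outside_sd_area", "traj_periodicity",
    "speed_dev_area", "speed_outside_sd_area", "speed_periodicity",
    "speed_skewness", "accel_xcorr", "elbow_rom_deg",
)

_SIDES = {"left": ("LS", "LE", "LW"), "right": ("RS", "RE", "RW")}


@dataclass(frozen=True)
class MetricsConfig:
    """Knobs of the metric stage.

    window_s:
        Length of the moving-average window (seconds, default 2): both the
        window of the moving statistics and the normaliser of the area
        metrics.
    rate_hz:
        Uniform resampling rate (default 30, the nominal acquisition rate).
    bout_threshold_fraction:
        Bout threshold as a fraction of the maximum wrist speed
        (default 0.05).
    periodicity_min_lag_s:
        Smallest autocorrelation lag considered a period (default 0.25 s;
        shorter lags are dominated by sample-to-sample smoothness).
    xcorr_mode:
        ``"zero_lag"`` (default) or ``"max_lag"`` for the bilateral
        acceleration correlation.
    restrict_to_bouts:
        Evaluate area/skewness/ROM metrics only on bout samples
        (default True).
    """

    window_s: float = 2.0
    rate_hz: float = 30.0
    bout_threshold_fraction: float = 0.05
    periodicity_min_lag_s: float = 0.25
    xcorr_mode: str = "zero_lag"
    restrict_to_bouts: bool = True

    def __post_init__(self) -> None:
        if self.window_s <= 0 or self.rate_hz <= 0:
            raise ValueError("window_s and rate_hz must be positive")
        if not 0 < self.bout_threshold_fraction < 1:
            raise ValueError("bout_threshold_fraction must be in (0, 1)")
        if self.xcorr_mode not in ("zero_lag", "max_lag"):
            raise ValueError("xcorr_mode must be 'zero_lag' or 'max_lag'")


@dataclass
class KinematicSeries:
    """Uniform-rate positions and derivatives for all points of interest.

    ``position`` is ``(n, n_poi, 3)`` mm on the uniform clock ``times_s``;
    ``velocity``/``acceleration`` are central-difference derivatives
    (one-sided at the two end samples), ``speed``/``accel_mag`` their
    Euclidean norms. Columns of unusable PoIs are NaN.
    """

    times_s: np.ndarray
    position: np.ndarray
    sample_rate_hz: float
    poi_names: tuple[str, ...]
    window_s: float = 2.0
    velocity: np.ndarray | None = None
    speed: np.ndarray | None = None
    acceleration: np.ndarray | None = None
    accel_mag: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return int(self.times_s.size)

    def poi_index(self, poi: str) -> int:
        return self.poi_names.index(poi)


@dataclass
class BoutSet:
    """Activity bouts of one wrist: intervals of supra-threshold speed."""

    intervals: list[tuple[float, float]]
    n_bouts: int
    mean_duration_s: float
    sd_duration_s: float
    movement_pct: float
    speed_threshold_mm_s: float
    mask: np.ndarray | None = None  # per-sample bout membership

    def to_dict(self) -> dict:
        return {
            "intervals": [[float(a), float(b)] for a, b in self.intervals],
            "n_bouts": self.n_bouts,
            "mean_duration_s": self.mean_duration_s,
            "sd_duration_s": self.sd_duration_s,
            "movement_pct": self.movement_pct,
            "speed_threshold_mm_s": self.speed_threshold_mm_s,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BoutSet":
        return cls(intervals=[tuple(x) for x in d["intervals"]],
                   n_bouts=d["n_bouts"], mean_duration_s=d["mean_duration_s"],
                   sd_duration_s=d["sd_duration_s"],
                   movement_pct=d["movement_pct"],
                   speed_threshold_mm_s=d["speed_threshold_mm_s"])


@dataclass
class GMMetricSet:
    """The nine metric values per side grouping, plus bout statistics.

    ``metrics`` maps ``left`` / ``right`` / ``combined`` to the nine metric
    keys; a value is None when it could not be computed (reason recorded in
    ``metadata['null_reasons']``). The combined value is the mean of the two
    sides for the unilateral metrics; the bilateral acceleration
    cross-correlation lives under ``combined`` only.
    """

    metrics: dict
    bouts: dict
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "metrics": self.metrics,
            "bouts": {side: (b.to_dict() if isinstance(b, BoutSet) else b)
                      for side, b in self.bouts.items()},
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GMMetricSet":
        bouts = {side: (BoutSet.from_dict(b) if b is not None else None)
                 for side, b in d["bouts"].items()}
        return cls(metrics=d["metrics"], bouts=bouts,
                   metadata=d.get("metadata", {}))


# ---------------------------------------------------------------------------
# Resampling and derivatives
# ---------------------------------------------------------------------------


def resample_uniform(traj: Trajectory3D, rate_hz: float = 30.0,
                     window_s: float = 2.0) -> KinematicSeries:
    """Cubic-spline resampling of all usable PoIs onto one uniform clock.

    The grid spans the intersection of the usable PoIs' valid spans so that
    inter-PoI quantities (elbow angle, bilateral correlation) share a clock.
    Each PoI must have >= 4 valid samples spanning at least twice the
    moving-average window.
    """
    dt_ms = 1000.0 / rate_hz
    t0 = -np.inf
    t1 = np.inf
    usable = []
    for pi, poi in enumerate(traj.poi_names):
        if not traj.usable[pi]:
            continue
        valid = traj.valid_mask(pi)
        tv = traj.slot_times_ms[valid]
        if tv.size < 4:
            raise ValueError(f"{poi}: fewer than 4 valid samples")
        if tv[-1] - tv[0] < 2 * window_s * 1000.0:
            raise ValueError(f"{poi}: valid span {(tv[-1] - tv[0]) / 1000:.2f} s "
                             f"is shorter than twice the window ({window_s} s)")
        t0 = max(t0, tv[0])
        t1 = min(t1, tv[-1])
        usable.append(pi)
    if not usable:
        raise ValueError("no usable PoI to resample")
    if t1 - t0 < 2 * window_s * 1000.0:
        raise ValueError("common valid span across PoIs is too short")

    n = int(math.floor((t1 - t0) / dt_ms)) + 1
    grid_ms = t0 + dt_ms * np.arange(n)
    pos = np.full((n, len(traj.poi_names), 3), np.nan)
    for pi in usable:
        valid = traj.valid_mask(pi)
        tv = traj.slot_times_ms[valid]
        for ax in range(3):
            spline = CubicSpline(tv, traj.xyz[valid, pi, ax])
            pos[:, pi, ax] = spline(grid_ms)
    return KinematicSeries(times_s=(grid_ms - grid_ms[0]) / 1000.0,
                           position=pos, sample_rate_hz=rate_hz,
                           poi_names=traj.poi_names, window_s=window_s)


def differentiate(series: KinematicSeries) -> KinematicSeries:
    """Central-difference velocity and acceleration plus their magnitudes."""
    if series.n_samples < 5:
        raise ValueError("need at least 5 samples to differentiate")
    dt = 1.0 / series.sample_rate_hz
    vel = np.gradient(series.position, dt, axis=0)
    acc = np.gradient(vel, dt, axis=0)
    series.velocity = vel
    series.acceleration = acc
    series.speed = np.linalg.norm(vel, axis=2)
    series.accel_mag = np.linalg.norm(acc, axis=2)
    return series


# ---------------------------------------------------------------------------
# Moving statistics and area metrics
# ---------------------------------------------------------------------------


def _window_samples(window_s: float, rate_hz: float) -> int:
    w = int(round(window_s * rate_hz)) + 1
    if w % 2 == 0:
        w += 1
    return w


def moving_stats(series: np.ndarray, window_s: float,
                 rate_hz: float) -> tuple[np.ndarray, np.ndarray]:
    """Centered moving average and sample SD with shrinking edge windows.

    The window holds ``round(window_s * rate) + 1`` samples, forced odd so
    that it is symmetric; near the record edges the window shrinks to what
    is available.
    """
    x = np.asarray(series, dtype=float)
    w = _window_samples(window_s, rate_hz)
    if w >= x.size:
        raise ValueError(f"window of {w} samples must be shorter than the "
                         f"record ({x.size} samples)")
    s = pd.Series(x)
    ma = s.rolling(w, center=True, min_periods=1).mean().to_numpy()
    sd = s.rolling(w, center=True, min_periods=2).std(ddof=1).fillna(0.0).to_numpy()
    return ma, sd


def _masked_trapezoid(y: np.ndarray, dt: float,
                      mask: np.ndarray | None) -> float:
    """Trapezoidal integral of ``y`` over the (possibly masked) record.

    With a mask, each maximal True run is integrated separately and the
    pieces summed; single-sample runs contribute ``y * dt`` (rectangle) so
    isolated samples are not silently dropped.
    """
    if mask is None:
        return float(np.trapezoid(y, dx=dt))
    total = 0.0
    for a, b in _runs(mask):
        if b - a == 1:
            total += float(y[a]) * dt
        else:
            total += float(np.trapezoid(y[a:b], dx=dt))
    return total


def metric_dev_area(series: np.ndarray, window_s: float, rate_hz: float,
                    domain_mask: np.ndarray | None = None) -> float:
    """Area between a profile and its moving average, per window length.

    Trapezoidal integral of ``|series - MA|`` over time (restricted to the
    domain mask when given), divided by the moving-average window length.
    Used for the wrist-trajectory area (per axis, summed by the caller) and
    the speed-profile area.
    """
    x = np.asarray(series, dtype=float)
    ma, _ = moving_stats(x, window_s, rate_hz)
    dev = np.abs(x - ma)
    return _masked_trapezoid(dev, 1.0 / rate_hz, domain_mask) / window_s


def metric_outside_sd_area(series: np.ndarray, window_s: float, rate_hz: float,
                           normalization: str = "window",
                           domain_mask: np.ndarray | None = None) -> float:
    """Area outside the moving-SD band around the moving average.

    Over samples where ``|series - MA|`` strictly exceeds the moving SD,
    the exceedance ``|series - MA| - SD`` is accumulated (sample sum times
    the sampling interval). ``normalization="outside_samples"`` divides by
    the accumulated time of the exceeding samples (their mean exceedance);
    ``"window"`` divides by the window length. Returns 0 when no sample is
    outside the band.
    """
    if normalization not in ("window", "outside_samples"):
        raise ValueError("normalization must be 'window' or 'outside_samples'")
    x = np.asarray(series, dtype=float)
    ma, sd = moving_stats(x, window_s, rate_hz)
    dev = np.abs(x - ma)
    outside = dev > sd
    if domain_mask is not None:
        outside = outside & domain_mask
    n_out = int(outside.sum())
    if n_out == 0:
        return 0.0
    dt = 1.0 / rate_hz
    area = float((dev[outside] - sd[outside]).sum()) * dt
    if normalization == "outside_samples":
        return area / (n_out * dt)
    return area / window_s


# ---------------------------------------------------------------------------
# Periodicity, skewness, bilateral correlation
# ---------------------------------------------------------------------------


def metric_periodicity(detrended: np.ndarray, rate_hz: float,
                       min_lag_s: float = 0.25) -> float:
    """Peak of the biased normalized autocorrelation, in [0, 1].

    ``r(k) = sum_t x_t x_{t+k} / sum_t x_t^2`` is evaluated for lags from
    ``min_lag_s`` up to half the record; the maximum is returned, with
    negative peaks clipped to 0. The input must already be detrended
    (moving average removed) and at least 4 s long.
    """
    x = np.asarray(detrended, dtype=float)
    n = x.size
    if n < 4 * rate_hz:
        raise ValueError("periodicity needs at least 4 s of data")
    denom = float(np.dot(x, x))
    if denom == 0.0:
        raise ValueError("zero-variance series: periodicity undefined")
    full = signal.correlate(x, x, mode="full", method="auto")
    acf = full[n - 1:] / denom
    k0 = max(int(round(min_lag_s * rate_hz)), 1)
    k1 = n // 2
    if k0 > k1:
        raise ValueError("record too short for the minimum lag")
    peak = float(acf[k0:k1 + 1].max())
    return min(max(peak, 0.0), 1.0)


def metric_skewness(speed_series: np.ndarray) -> float:
    """Adjusted Fisher-Pearson sample skewness of the wrist speed."""
    v = np.asarray(speed_series, dtype=float)
    if v.size < 20:
        raise ValueError("skewness needs at least 20 samples")
    if np.ptp(v) == 0:
        raise ValueError("zero-variance series: skewness undefined")
    return float(stats.skew(v, bias=False))


def metric_accel_xcorr(left_accel: np.ndarray, right_accel: np.ndarray,
                       mode: str = "zero_lag",
                       domain_mask: np.ndarray | None = None) -> float:
    """Correlation of the left and right wrist acceleration profiles.

    ``zero_lag`` (default): Pearson correlation at zero lag over the
    evaluated samples, emphasising synchrony. ``max_lag``: maximum of the
    normalized cross-correlation of the mean-removed signals over all lags
    up to half the record (requires contiguous input, so the domain mask is
    ignored there).
    """
    a = np.asarray(left_accel, dtype=float)
    b = np.asarray(right_accel, dtype=float)
    if a.shape != b.shape:
        raise ValueError("left and right series must share a time grid")
    if mode == "zero_lag":
        if domain_mask is not None:
            a = a[domain_mask]
            b = b[domain_mask]
        if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
            raise ValueError("zero variance on one side: correlation undefined")
        return float(np.corrcoef(a, b)[0, 1])
    if mode == "max_lag":
        a = a - a.mean()
        b = b - b.mean()
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            raise ValueError("zero variance on one side: correlation undefined")
        n = a.size
        full = signal.correlate(a, b, mode="full", method="auto")
        norm = math.sqrt(float(np.dot(a, a)) * float(np.dot(b, b)))
        lags = signal.correlation_lags(n, n, mode="full")
        keep = np.abs(lags) <= n // 2
        return float((full[keep] / norm).max())
    raise ValueError("mode must be 'zero_lag' or 'max_lag'")


def elbow_angle_series(shoulder: np.ndarray, elbow: np.ndarray,
                       wrist: np.ndarray, min_segment_mm: float = 10.0,
                       ) -> tuple[np.ndarray, int]:
    """Included elbow angle between upper-arm and forearm segments.

    ``angle = arccos( (S-E)·(W-E) / (|S-E| |W-E|) )`` in degrees in
    [0, 180]; 180 is the fully extended arm. Samples where any coordinate
    is missing or a segment is shorter than ``min_segment_mm`` are NaN and
    counted. Returns ``(angles_deg, n_skipped)``.
    """
    s = np.asarray(shoulder, dtype=float)
    e = np.asarray(elbow, dtype=float)
    w = np.asarray(wrist, dtype=float)
    ua = s - e
    fa = w - e
    n_ua = np.linalg.norm(ua, axis=-1)
    n_fa = np.linalg.norm(fa, axis=-1)
    bad = ~np.isfinite(n_ua) | ~np.isfinite(n_fa) | (n_ua <= min_segment_mm) \
        | (n_fa <= min_segment_mm)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("...i,...i->...", ua, fa) / (n_ua * n_fa)
    angles = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    angles[bad] = np.nan
    return angles, int(bad.sum())


# ---------------------------------------------------------------------------
# Bouts
# ---------------------------------------------------------------------------


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs as half-open index ranges."""
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return []
    padded = np.concatenate(([False], m, [False])).astype(int)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def detect_bouts(speed_series: np.ndarray, rate_hz: float,
                 threshold_fraction: float = 0.05) -> BoutSet:
    """Detect activity bouts: maximal runs of supra-threshold wrist speed.

    The threshold is ``threshold_fraction`` times the maximum of the speed
    series (5% by default); samples strictly above it belong to a bout.
    An all-zero speed yields zero bouts and 0% movement, not an error.
    """
    v = np.asarray(speed_series, dtype=float)
    if v.size == 0 or np.nanmin(v) < 0:
        raise ValueError("speed must be non-negative and non-empty")
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold_fraction must be in (0, 1)")
    dt = 1.0 / rate_hz
    thr = threshold_fraction * float(np.nanmax(v))
    mask = v > thr
    runs = _runs(mask)
    durations = np.array([(b - a) * dt for a, b in runs])
    intervals = [(a * dt, b * dt) for a, b in runs]
    n = len(runs)
    return BoutSet(
        intervals=intervals,
        n_bouts=n,
        mean_duration_s=float(durations.mean()) if n else 0.0,
        sd_duration_s=float(durations.std(ddof=1)) if n >= 2 else 0.0,
        movement_pct=100.0 * float(mask.sum()) / v.size,
        speed_threshold_mm_s=thr,
        mask=mask,
    )


# ---------------------------------------------------------------------------
# Top-level metric set
# ---------------------------------------------------------------------------


def compute_all_metrics(traj: Trajectory3D,
                        config: MetricsConfig | None = None) -> GMMetricSet:
    """Resample, differentiate, detect bouts, and compute all nine metrics.

    Per side, the wrist drives metrics 1-7 and the shoulder/elbow/wrist
    triple drives the elbow-angle ROM; the bilateral acceleration
    correlation is evaluated on the intersection of both sides' bouts and
    reported under ``combined``. A side whose wrist could not be
    reconstructed gets null metrics with the reason recorded. Deterministic
    for fixed input and config.
    """
    if config is None:
        config = MetricsConfig()
    null_reasons: dict[str, str] = {}
    metrics = {side: {k: None for k in METRIC_KEYS}
               for side in ("left", "right", "combined")}
    bouts: dict[str, BoutSet | None] = {"left": None, "right": None}

    try:
        ks = differentiate(resample_uniform(traj, config.rate_hz, config.window_s))
    except ValueError as exc:
        return GMMetricSet(metrics=metrics, bouts=bouts,
                           metadata={"null_reasons": {"all": str(exc)},
                                     "config": asdict(config)})

    side_masks: dict[str, np.ndarray | None] = {}
    for side, (s_poi, e_poi, w_poi) in _SIDES.items():
        wi = ks.poi_index(w_poi)
        m = metrics[side]
        if not traj.usable[wi]:
            null_reasons[side] = f"{w_poi} unusable"
            side_masks[side] = None
            continue
        speed = ks.speed[:, wi]
        bout = detect_bouts(speed, config.rate_hz, config.bout_threshold_fraction)
        bouts[side] = bout
        domain = bout.mask if config.restrict_to_bouts else np.ones_like(bout.mask)
        side_masks[side] = domain

        # 1-3: trajectory metrics, per axis
        pos = ks.position[:, wi, :]
        m["traj_dev_area"] = sum(
            metric_dev_area(pos[:, ax], config.window_s, config.rate_hz, domain)
            for ax in range(3))
        m["traj_outside_sd_area"] = sum(
            metric_outside_sd_area(pos[:, ax], config.window_s, config.rate_hz,
                                   "outside_samples", domain)
            for ax in range(3))
        try:
            vals = []
            for ax in range(3):
                ma, _ = moving_stats(pos[:, ax], config.window_s, config.rate_hz)
                vals.append(metric_periodicity(pos[:, ax] - ma, config.rate_hz,
                                               config.periodicity_min_lag_s))
            m["traj_periodicity"] = float(np.mean(vals))
        except ValueError as exc:
            null_reasons[f"{side}.traj_periodicity"] = str(exc)

        # 4-7: speed metrics, scalar profile
        m["speed_dev_area"] = metric_dev_area(speed, config.window_s,
                                              config.rate_hz, domain)
        m["speed_outside_sd_area"] = metric_outside_sd_area(
            speed, config.window_s, config.rate_hz, "window", domain)
        try:
            ma, _ = moving_stats(speed, config.window_s, config.rate_hz)
            m["speed_periodicity"] = metric_periodicity(
                speed - ma, config.rate_hz, config.periodicity_min_lag_s)
        except ValueError as exc:
            null_reasons[f"{side}.speed_periodicity"] = str(exc)
        try:
            m["speed_skewness"] = metric_skewness(speed[domain])
        except ValueError as exc:
            null_reasons[f"{side}.speed_skewness"] = str(exc)

        # 9: elbow angle ROM over evaluated samples
        si, ei = ks.poi_index(s_poi), ks.poi_index(e_poi)
        if traj.usable[si] and traj.usable[ei]:
            angles, _ = elbow_angle_series(ks.position[:, si, :],
                                           ks.position[:, ei, :], pos)
            sel = domain & np.isfinite(angles)
            if sel.any():
                m["elbow_rom_deg"] = float(angles[sel].max() - angles[sel].min())
            else:
                null_reasons[f"{side}.elbow_rom_deg"] = "no evaluable elbow sample"
        else:
            null_reasons[f"{side}.elbow_rom_deg"] = \
                f"{s_poi} or {e_poi} unusable"

    # 8: bilateral acceleration correlation on the bout intersection
    if side_masks.get("left") is not None and side_masks.get("right") is not None:
        both = side_masks["left"] & side_masks["right"]
        li = ks.poi_index("LW")
        ri = ks.poi_index("RW")
        if both.sum() >= 4 * config.rate_hz:
            try:
                metrics["combined"]["accel_xcorr"] = metric_accel_xcorr(
                    ks.accel_mag[:, li], ks.accel_mag[:, ri],
                    mode=config.xcorr_mode,
                    domain_mask=both if config.xcorr_mode == "zero_lag" else None)
            except ValueError as exc:
                null_reasons["combined.accel_xcorr"] = str(exc)
        else:
            null_reasons["combined.accel_xcorr"] = \
                "bout overlap shorter than 4 s"
    else:
        null_reasons["combined.accel_xcorr"] = "one side unusable"

    # combined = mean of sides for the unilateral metrics
    for key in METRIC_KEYS:
        if key == "accel_xcorr":
            continue
        lv = metrics["left"][key]
        rv = metrics["right"][key]
        if lv is not None and rv is not None:
            metrics["combined"][key] = 0.5 * (lv + rv)
        elif lv is not None or rv is not None:
            metrics["combined"][key] = lv if lv is not None else rv

    meta = {
        "config": asdict(config),
        "null_reasons": null_reasons,
        "combined_rule": "mean of sides (unilateral metrics); "
                         "accel_xcorr is bilateral, combined only",
    }
    return GMMetricSet(metrics=metrics, bouts=bouts, metadata=meta)
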