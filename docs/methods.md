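# Methods

`gm3d` quantifies infant general movements (GM) from a single consumer
RGB-D camera and a markerless 2D pose tracker. This note records the model
the package implements, the parameters that matter, what the synthetic-data
generator does and does not emulate, and the numerical choices taken where
the design was genuinely open.

## Sensing model and assumptions

The input is a recording of a supine infant by an RGB-D sensor whose color
stream (nominally 30 fps, 1280×720) and depth stream (nominally 30 fps,
640×480, millimetre-coded) run on separate, only nominally constant clocks.
Six upper-body points of interest (PoI) — left/right shoulder, elbow, wrist
(LS, RS, LE, RE, LW, RW) — are tracked in the RGB stream by a pose
estimator that reports sub-pixel (u, v) coordinates plus a confidence in
[0, 1] per frame. Depth pixels encode range along the optical axis; the
value 0 marks the "black area" where the stereo IR pair produced no range.
The two streams are factory pre-registered, so RGB pixels map to depth
pixels by proportional rescaling (u·w_d/w_r, v·h_d/h_r); residual spatial
misalignment is handled downstream as a temporal artifact, not corrected
geometrically. Camera axes: x right, y down, z forward; all 3D output is in
millimetres in the depth camera frame.

## Stream alignment

Frames are re-paired from their measured timestamps. An RGB/depth pair may
share a slot only when |Δt| is strictly below half the nominal sampling
interval (17 ms at 30 fps); a frame with no partner occupies a slot alone,
with a gap recorded in the other column. Among all monotone (non-crossing)
pairings satisfying the gate, `align_streams` returns the one that first
maximises the number of pairs and then minimises the total |Δt|. This is
computed exactly by a sparse chain dynamic program: each frame has at most
a few candidate partners inside the tolerance window, and a Fenwick
prefix-maximum over depth columns yields best predecessors in
O(m log n) for m candidate pairs. A simple two-pointer greedy merge is
equivalent in the common case but provably suboptimal when a dropped frame
coincides with a stream offset near the tolerance boundary, which is why
the optimal matching is used. Slot time is the mean of the paired
timestamps, else the surviving stream's timestamp.

Ties at exactly |Δt| = tolerance count as *not* aligned (strict
inequality). A configured tolerance at or above the nominal interval is
rejected as ambiguous. The bound is derived from the nominal rate, not the
measured one, even if a stream runs slow.

## Depth cleaning and 3D reconstruction

Per PoI, samples pass through a fixed-order chain; the order matters and is
part of the contract:

1. **Alignment slotting** — slots missing either stream are flagged
   `alignment_gap`.
2. **Confidence gate** — frames with confidence < 0.6 (strict) are flagged
   `low_confidence`. Occlusions both corrupt the depth estimate and lower
   the tracker's confidence, so gating must precede derivative screening or
   an occlusion spike would be mis-attributed.
3. **Depth sampling** — the median of valid (nonzero) pixels in a 3×3 patch
   around the mapped pixel; an all-invalid patch flags `black_area`. The
   patch median buys robustness to single-pixel depth noise at a sub-pixel
   track location.
4. **Despiking** — the forward first difference of the depth coordinate,
   |z(t_k) − z(t_last)| / Δt over surviving samples, is compared with a
   physical bound on subject speed (default 2000 mm/s, a generous limit for
   infant hand motion). A violation flags the *later* sample (`depth_jump`)
   and the difference is re-anchored at the last survivor, so a genuine
   level change lasting several frames cannot cascade into mass deletion.
5. **Gap filling** — interior runs of flagged samples are refilled by one
   not-a-knot cubic spline per channel, u, v and z independently, fit
   through all surviving samples. Leading/trailing gaps are never
   extrapolated; they are flagged `edge_unfilled` and excluded downstream.
   u and v share the z gap-filling policy so back-projection always has
   complete pixel data.
6. **Back-projection** — x = (u_d − c_x)·z/f_x, y = (v_d − c_y)·z/f_y,
   z = depth.

Every output sample is exactly one of untouched, spline-filled, or
flagged-invalid; the per-reason counts partition the record and are
reported in the QC output. A PoI with fewer than 4 surviving samples is
marked unusable; below 50% survival a warning is recorded.

The not-a-knot boundary condition is used for every spline in the package
because it reproduces cubic polynomials exactly, which anchors the test
contracts; a natural spline does not.

## Metrics

Metrics are computed on a uniform clock (default 30 Hz) obtained by cubic
spline resampling over the intersection of the usable PoIs' valid spans.
Velocity and acceleration are central differences (one-sided at the two end
samples); speed and acceleration magnitude are Euclidean norms.

Activity bouts per wrist are maximal runs with speed strictly above 5% of
that wrist's maximum speed ("maximum" is the literal maximum of the cleaned
series — despiking has already removed artifact velocities; a percentile
alternative is available but off by default). Metric evaluation is
restricted to bout samples by default to limit the influence of quiescent
intervals; `restrict_to_bouts = false` evaluates the whole record.

With MA/SD the centered moving average and sample standard deviation over a
2 s window (round(w·rate)+1 samples forced odd, shrinking at the record
edges):

1. **Trajectory deviation area** — trapezoidal ∫|p − MA(p)| dt per axis,
   summed over axes, divided by the window length (units mm).
2. **Trajectory outside-SD area** — Σ (|p − MA| − SD)·Δt over samples where
   |p − MA| > SD (strict), divided by the accumulated time of those samples
   (their mean exceedance); per axis, summed. Zero when no sample exceeds —
   a zero-SD constant record cannot strictly exceed a zero band.
3. **Trajectory periodicity** — the peak of the biased normalized
   autocorrelation of the MA-detrended signal over lags from 0.25 s to half
   the record, per axis, averaged; negative peaks clip to 0. The estimator
   is deliberately parameter-light; lags below 0.25 s are excluded because
   they measure smoothness, not rhythm.
4. **Speed deviation area** — as (1) on the scalar speed profile (mm/s).
5. **Speed outside-SD area** — as (2) on speed, but normalized by the
   window length.
6. **Speed periodicity** — as (3) on detrended speed.
7. **Speed skewness** — adjusted Fisher–Pearson sample skewness of the
   within-bout speed samples.
8. **Bilateral acceleration correlation** — Pearson correlation at zero lag
   between left and right wrist acceleration magnitudes over the
   intersection of both sides' bouts. Zero lag is the default because the
   construct of interest is synchrony; a max-over-lags variant is available
   behind `xcorr_mode = max_lag`.
9. **Elbow-angle range of motion** — the included angle
   arccos[(S−E)·(W−E)/(|S−E||W−E|)] in degrees ∈ [0, 180], with ROM the
   max − min over evaluated bout samples; slots with a missing PoI or a
   segment under 10 mm are skipped and counted. ROM is evaluated within
   bouts, consistent with the other metrics.

Axis policy: trajectory metrics are per-axis (summed for areas, averaged
for periodicity); velocity metrics use the scalar speed. The choice is
recorded in the report metadata. The "combined" grouping is the mean of the
two sides for the unilateral metrics; metric 8 is inherently bilateral and
is reported under "combined" only. No low-pass filtering is applied before
differentiation by default so that the naive oracles match exactly;
optional zero-phase smoothing exists but is off.

Degenerate inputs degrade to explicit nulls with reasons (zero-variance
periodicity/skewness, an unusable wrist, bout overlap under 4 s), never to
silent omissions.

## Synthetic data generator

Because no public recording of this kind exists, the generator produces the
four observables plus complete ground truth. Latent kinematics are sums of
sinusoids per PoI and axis around a supine base pose at ~0.9 m range:
2–3 voluntary components in 0.3–2 Hz with per-axis amplitudes of ~40 mm
(wrists), 20 mm (elbows), 6 mm (shoulders), plus a 3–8 Hz low-amplitude
tremor band (1.5 mm RMS). Left/right pairs mix a shared component set
(mirrored in x) with independent sets using weights √ρ and √(1−ρ), so the
bilateral coupling ρ is a single dial; a smooth on/off activity envelope
creates quiescent intervals for hypokinetic scenarios. Everything is an
explicit function of time, so ground truth exists at any timestamp and
every metric's expected behaviour is derivable analytically or by cheap
quadrature.

Sensor effects: both clocks get Gaussian timestamp jitter (2 ms SD,
clipped) and random frame drops (2%); a uniform clock offset separates the
streams. Depth frames are a background plane (1400 mm) with a correct-depth
disc rendered around each projected PoI — PoI-local rendering, not a body
model, because the pipeline only samples depth near tracked points.
Artifacts are injected exactly as the countermeasures expect them:
black-area discs (5% of frames per PoI), occlusions (depth biased +150 mm
with confidence dropped below 0.6 on the time-paired RGB frame, 5%), and
single-frame ±400 mm spikes; all injected frame indices are recorded.

What the generator does **not** emulate: pose-estimator coordinate error
beyond confidence dropouts, anatomically inconsistent landmark drift
(a tracker may lock onto different spots across frames), lens distortion,
depth noise texture, limb self-occlusion geometry, or a biomechanically
consistent kinematic chain. Passing tests therefore demonstrate that the
pipeline recovers known kinematics through the modelled artifact
mechanisms — not that it is robust to every failure mode of real trackers.

## Problem sizes and determinism

Default desk-scale runs use 8–30 s recordings; the packaged property checks
use 20 recordings per condition (20 s for artifact recovery, 15 s for
cohort orderings — long enough for the 2 s window and ≥4 s periodicity
requirement with room to spare). All randomness flows from a single integer
seed through `numpy.random.default_rng`; identical seeds give byte-identical
emitted files and reports, and the run manifest (config echo, version,
input digests) suffices to reproduce an analysis.

## Known limitations

* Proportional pixel rescaling assumes well-registered streams; strong lens
  distortion or registration error would need the full reprojection path.
* The despiking bound is a constant; a statistically adaptive threshold
  might do better near genuine fast movements.
* Periodicity via an autocorrelation peak saturates for multi-periodic
  signals and is bounded by the biased-estimator factor (1 − lag/n) on
  short records.
* Clinical interpretation (typical vs atypical development) is explicitly
  out of scope; cohort checks assert direction of metric differences on
  synthetic data only.
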