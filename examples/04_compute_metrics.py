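"""Compute the nine GM quantification metrics and bout statistics.

The metric stage resamples to a uniform 30 Hz clock, detects activity bouts
(wrist speed above 5% of its maximum) and evaluates the metrics within
bouts: four moving-average area metrics, two periodicity metrics, speed
skewness, the bilateral acceleration correlation, and the elbow-angle
range of motion.
"""

from gm3d.depth_reconstruction import reconstruct_trajectories
from gm3d.gm_metrics import compute_all_metrics
from gm3d.stream_sync import align_streams
from gm3d.synthetic_data import ScenarioSpec, generate_recording

rec = generate_recording(ScenarioSpec(seed=1, duration_s=30.0,
                                      bilateral_coupling=0.6))
al = align_streams(rec.rgb_ts, rec.depth_ts)
traj = reconstruct_trajectories(rec.track, rec.depth, al, rec.spec.camera)
ms = compute_all_metrics(traj)

print(f"{'metric':24s} {'left':>10s} {'right':>10s} {'combined':>10s}")
for key in ms.metrics["left"]:
    row = [ms.metrics[s][key] for s in ("left", "right", "combined")]
    cells = " ".join(f"{v:10.3f}" if v is not None else f"{'--':>10s}"
                     for v in row)
    print(f"{key:24s} {cells}")
for side in ("left", "right"):
    b = ms.bouts[side]
    print(f"bouts {side}: n={b.n_bouts}, mean {b.mean_duration_s:.1f} s, "
          f"movement {b.movement_pct:.1f}% of the recording")
print("Area metrics are mm per 2 s window; periodicity is an "
      "autocorrelation peak in [0,1]; the bilateral acceleration "
      "correlation reflects the generator's coupling of 0.6.")
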