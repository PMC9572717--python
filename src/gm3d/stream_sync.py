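"""Time alignment of the RGB and depth frame streams and spline gap filling.

Consumer RGB-D sensors run the color and depth imagers on separate, only
nominally constant clocks, so frames have to be re-paired from their
measured timestamps. Three situations arise and are handled per slot:

1. an RGB frame has no depth frame within the tolerance -> a gap slot is
   inserted in the depth column;
2. a depth frame has no RGB frame within the tolerance -> a gap slot is
   inserted in the RGB column;
3. an RGB/depth pair differs by less than half the nominal sampling
   interval (< 17 ms at 30 fps) -> the two frames share one aligned slot.

All interior gaps produced this way are later filled by cubic-spline
interpolation; leading/trailing gaps are never extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from gm3d.formats_io import TimestampSeries

__all__ = ["GAP", "AlignmentResult", "GappedSeries", "align_streams",
           "fill_gaps_spline", "write_alignment_csv"]


class _Gap:
    """Sentinel marking a slot where one stream has no frame."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "GAP"


GAP = _Gap()

_NO_FRAME = -1  # internal integer sentinel in index arrays


@dataclass
class AlignmentResult:
    """Slot-wise pairing of RGB and depth frame indices.

    ``rgb_index`` / ``depth_index`` are per-slot frame indices with -1 where
    a gap slot was inserted; :attr:`pairs` exposes the same information with
    the :data:`GAP` sentinel. Slot time is the mean of the paired timestamps
    for aligned slots, else the surviving stream's timestamp.
    """

    rgb_index: np.ndarray
    depth_index: np.ndarray
    slot_times_ms: np.ndarray
    tolerance_ms: float

    @property
    def n_slots(self) -> int:
        return int(self.rgb_index.size)

    @property
    def pairs(self) -> list[tuple]:
        return [
            (GAP if r == _NO_FRAME else int(r), GAP if d == _NO_FRAME else int(d))
            for r, d in zip(self.rgb_index, self.depth_index)
        ]

    @property
    def inserted_rgb_gaps(self) -> np.ndarray:
        """Slot indices where the RGB column holds a gap."""
        return np.flatnonzero(self.rgb_index == _NO_FRAME)

    @property
    def inserted_depth_gaps(self) -> np.ndarray:
        """Slot indices where the depth column holds a gap."""
        return np.flatnonzero(self.depth_index == _NO_FRAME)


class _Fenwick:
    """Prefix-maximum tree over columns, keyed lexicographically."""

    __slots__ = ("vals",)
    _NEG = (-1, 0.0, -1)

    def __init__(self, n: int):
        self.vals = [self._NEG] * (n + 1)

    def update(self, pos: int, value: tuple) -> None:
        pos += 1
        while pos < len(self.vals):
            if value > self.vals[pos]:
                self.vals[pos] = value
            pos += pos & -pos

    def query(self, pos: int) -> tuple:
        """Best value over columns [0, pos]."""
        best = self._NEG
        pos += 1
        while pos > 0:
            if self.vals[pos] > best:
                best = self.vals[pos]
            pos -= pos & -pos
        return best


def _optimal_pairs(tr: np.ndarray, td: np.ndarray,
                   tol: float) -> list[tuple[int, int]]:
    """Optimal order-preserving matching of the two frame streams.

    Among monotone pairings restricted to ``|dt| < tol``, maximises the
    number of matched pairs and, among those, minimises the total ``|dt|``.
    Candidate partners per frame are the handful of opposite-stream frames
    inside the tolerance window, so the chain DP is sparse; a Fenwick tree
    provides best-predecessor queries over depth columns.
    """
    cells: list[tuple[int, int, float]] = []
    lo = np.searchsorted(td, tr - tol, side="right")
    hi = np.searchsorted(td, tr + tol, side="left")
    for i in range(tr.size):
        for j in range(lo[i], hi[i]):
            dt = abs(tr[i] - td[j])
            if dt < tol:
                cells.append((i, j, dt))
    if not cells:
        return []
    fen = _Fenwick(td.size)
    # value = (npairs, -total_dt, cell_index); parent per cell for backtrack
    value: list[tuple] = [None] * len(cells)
    parent: list[int] = [-1] * len(cells)
    k = 0
    while k < len(cells):
        row = cells[k][0]
        row_end = k
        while row_end < len(cells) and cells[row_end][0] == row:
            row_end += 1
        # query all cells of this row before inserting any (keeps i' < i)
        for c in range(k, row_end):
            _, j, dt = cells[c]
            pred = fen.query(j - 1) if j > 0 else _Fenwick._NEG
            npairs = pred[0] + 1 if pred[0] >= 0 else 1
            cost = -pred[1] + dt if pred[0] >= 0 else dt
            value[c] = (npairs, -cost, c)
            parent[c] = pred[2]
        for c in range(k, row_end):
            fen.update(cells[c][1], value[c])
        k = row_end
    best = max(range(len(cells)), key=lambda c: value[c][:2])
    chain = []
    c = best
    while c >= 0:
        chain.append((cells[c][0], cells[c][1]))
        c = parent[c]
    chain.reverse()
    return chain


def align_streams(rgb_ts: TimestampSeries, depth_ts: TimestampSeries,
                  tolerance_ms: float | None = None) -> AlignmentResult:
    """Merge the two timestamp streams into aligned and gap slots.

    Frames are paired by the optimal order-preserving matching under the
    strict ``|dt| < tolerance_ms`` gate (most pairs, then smallest total
    ``|dt|``); every unmatched frame of either stream occupies a slot of
    its own, in time order, with a gap recorded in the other column. Every
    input frame of both streams lands in exactly one slot and the pairing
    is monotonic.

    ``tolerance_ms`` defaults to half the nominal sampling interval of the
    faster stream. A tolerance at or above the nominal interval would make
    pairing ambiguous and is rejected.
    """
    if tolerance_ms is None:
        tolerance_ms = min(rgb_ts.nominal_dt_ms, depth_ts.nominal_dt_ms) / 2.0
    if not tolerance_ms > 0:
        raise ValueError("tolerance_ms must be positive")
    nominal = min(rgb_ts.nominal_dt_ms, depth_ts.nominal_dt_ms)
    if tolerance_ms >= nominal:
        raise ValueError(
            f"tolerance {tolerance_ms} ms >= nominal interval {nominal:.2f} ms: "
            "pairing would be ambiguous")

    tr = rgb_ts.times_ms
    td = depth_ts.times_ms
    matched = _optimal_pairs(tr, td, tolerance_ms)
    matched_r = {i for i, _ in matched}
    matched_d = {j for _, j in matched}
    pair_of_r = dict(matched)

    rgb_idx: list[int] = []
    depth_idx: list[int] = []
    times: list[float] = []
    i = j = 0
    while i < tr.size or j < td.size:
        if i < tr.size and i in matched_r:
            jj = pair_of_r[i]
            # flush unmatched depth frames that precede this pair
            while j < jj:
                rgb_idx.append(_NO_FRAME)
                depth_idx.append(j)
                times.append(td[j])
                j += 1
            rgb_idx.append(i)
            depth_idx.append(jj)
            times.append(0.5 * (tr[i] + td[jj]))
            i += 1
            j = jj + 1
            continue
        if j < td.size and j in matched_d and i < tr.size:
            # this depth frame waits for a later RGB partner; rgb i is a gap
            rgb_idx.append(i)
            depth_idx.append(_NO_FRAME)
            times.append(tr[i])
            i += 1
            continue
        take_rgb = i < tr.size and (j >= td.size or tr[i] <= td[j])
        if take_rgb:
            rgb_idx.append(i)
            depth_idx.append(_NO_FRAME)
            times.append(tr[i])
            i += 1
        else:
            rgb_idx.append(_NO_FRAME)
            depth_idx.append(j)
            times.append(td[j])
            j += 1
    assert len(matched_d) == len(matched)
    return AlignmentResult(
        rgb_index=np.asarray(rgb_idx, dtype=int),
        depth_index=np.asarray(depth_idx, dtype=int),
        slot_times_ms=np.asarray(times, dtype=float),
        tolerance_ms=float(tolerance_ms),
    )


@dataclass
class GappedSeries:
    """A per-slot real-valued series where NaN marks a gap.

    After :func:`fill_gaps_spline`, ``filled_mask`` marks slots whose value
    was produced by interpolation and ``edge_unfilled`` marks leading or
    trailing gaps that were deliberately left open.
    """

    values: np.ndarray
    slot_times_ms: np.ndarray
    filled_mask: np.ndarray | None = field(default=None)
    edge_unfilled: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.slot_times_ms = np.asarray(self.slot_times_ms, dtype=float)
        if self.values.shape != self.slot_times_ms.shape:
            raise ValueError("values and slot_times_ms must have the same shape")


def fill_gaps_spline(series: GappedSeries) -> GappedSeries:
    """Fill interior gaps with a cubic spline through all observed samples.

    A single not-a-knot cubic spline is fit through every non-gap
    (time, value) point and evaluated at the interior gap times; observed
    samples are returned unchanged bit-for-bit. Leading and trailing gaps
    are left as NaN and flagged in ``edge_unfilled`` — extrapolating a cubic
    beyond its support is unbounded. At least 4 observed samples are
    required.
    """
    vals = series.values
    t = series.slot_times_ms
    observed = np.isfinite(vals)
    n_obs = int(observed.sum())
    if n_obs == 0:
        raise ValueError("cannot fill an all-gap series")
    if n_obs < 4:
        raise ValueError(f"spline gap filling needs >= 4 observed samples, got {n_obs}")
    first, last = np.flatnonzero(observed)[[0, -1]]
    interior_gap = ~observed
    edge = np.zeros_like(observed)
    edge[:first] = interior_gap[:first]
    edge[last + 1:] = interior_gap[last + 1:]
    interior_gap[:first] = False
    interior_gap[last + 1:] = False

    out = vals.copy()
    if interior_gap.any():
        spline = CubicSpline(t[observed], vals[observed])
        out[interior_gap] = spline(t[interior_gap])
    return GappedSeries(values=out, slot_times_ms=t.copy(),
                        filled_mask=interior_gap, edge_unfilled=edge)


def write_alignment_csv(align: AlignmentResult, path) -> None:
    """Emit the per-slot alignment table (slot, rgb_index, depth_index, time)."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["slot", "rgb_index", "depth_index", "slot_time_ms"])
        for s in range(align.n_slots):
            r = align.rgb_index[s]
            d = align.depth_index[s]
            w.writerow([s,
                        "" if r == _NO_FRAME else int(r),
                        "" if d == _NO_FRAME else int(d),
                        repr(float(align.slot_times_ms[s]))])
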