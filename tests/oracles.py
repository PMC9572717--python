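"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive (explicit loops, dynamic programming,
textbook formulas) and shares no code with the package internals.
"""

from __future__ import annotations

import numpy as np


def dp_alignment(rgb_times: np.ndarray, depth_times: np.ndarray,
                 tol_ms: float) -> set[tuple[int, int]]:
    """Optimal order-preserving matching by dynamic programming.

    Maximises the number of matched pairs with ``|dt| < tol`` and, among
    those, minimises the total ``|dt|``. Returns the set of matched
    (rgb_index, depth_index) pairs.
    """
    nr, nd = len(rgb_times), len(depth_times)
    NEG = (0, 0.0)
    npairs = np.zeros((nr + 1, nd + 1), dtype=int)
    cost = np.zeros((nr + 1, nd + 1))
    choice = np.zeros((nr + 1, nd + 1), dtype=np.int8)  # 0 skip r, 1 skip d, 2 pair
    for i in range(1, nr + 1):
        for j in range(1, nd + 1):
            best = (npairs[i - 1, j], cost[i - 1, j], 0)
            cand = (npairs[i, j - 1], cost[i, j - 1], 1)
            if (cand[0], -cand[1]) > (best[0], -best[1]):
                best = cand
            dt = abs(rgb_times[i - 1] - depth_times[j - 1])
            if dt < tol_ms:
                cand = (npairs[i - 1, j - 1] + 1, cost[i - 1, j - 1] + dt, 2)
                if (cand[0], -cand[1]) > (best[0], -best[1]):
                    best = cand
            npairs[i, j], cost[i, j], choice[i, j] = best
    pairs = set()
    i, j = nr, nd
    while i > 0 and j > 0:
        c = choice[i, j]
        if c == 2:
            pairs.add((i - 1, j - 1))
            i -= 1
            j -= 1
        elif c == 0:
            i -= 1
        else:
            j -= 1
    return pairs


def natural_cubic_spline(x: np.ndarray, y: np.ndarray,
                         xq: np.ndarray) -> np.ndarray:
    """Natural cubic spline by direct tridiagonal solve (textbook form)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    h = np.diff(x)
    A = np.zeros((n, n))
    b = np.zeros(n)
    A[0, 0] = A[-1, -1] = 1.0
    for i in range(1, n - 1):
        A[i, i - 1] = h[i - 1]
        A[i, i] = 2 * (h[i - 1] + h[i])
        A[i, i + 1] = h[i]
        b[i] = 3 * ((y[i + 1] - y[i]) / h[i] - (y[i] - y[i - 1]) / h[i - 1])
    c = np.linalg.solve(A, b)
    out = np.empty_like(np.asarray(xq, float))
    for k, q in enumerate(np.atleast_1d(xq)):
        i = min(max(np.searchsorted(x, q) - 1, 0), n - 2)
        dx = q - x[i]
        bi = (y[i + 1] - y[i]) / h[i] - h[i] * (2 * c[i] + c[i + 1]) / 3
        di = (c[i + 1] - c[i]) / (3 * h[i])
        out[k] = y[i] + bi * dx + c[i] * dx ** 2 + di * dx ** 3
    return out


def moving_stats_loop(x: np.ndarray, half: int) -> tuple[np.ndarray, np.ndarray]:
    """Centered moving mean/sample-SD with shrinking edges, per-window loops."""
    n = len(x)
    ma = np.empty(n)
    sd = np.empty(n)
    for i in range(n):
        w = x[max(i - half, 0):min(i + half + 1, n)]
        ma[i] = w.mean()
        sd[i] = w.std(ddof=1) if w.size > 1 else 0.0
    return ma, sd


def dev_area_loop(x: np.ndarray, ma: np.ndarray, dt: float, window_s: float,
                  mask: np.ndarray | None = None) -> float:
    """Trapezoidal area between a profile and its moving average."""
    dev = np.abs(x - ma)
    if mask is None:
        mask = np.ones(len(x), dtype=bool)
    total = 0.0
    i = 0
    n = len(x)
    while i < n:
        if not mask[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and mask[j + 1]:
            j += 1
        if j == i:
            total += dev[i] * dt
        else:
            for k in range(i, j):
                total += 0.5 * (dev[k] + dev[k + 1]) * dt
        i = j + 1
    return total / window_s


def outside_sd_loop(x: np.ndarray, ma: np.ndarray, sd: np.ndarray, dt: float,
                    window_s: float, normalization: str,
                    mask: np.ndarray | None = None) -> float:
    dev = np.abs(x - ma)
    total = 0.0
    count = 0
    for i in range(len(x)):
        if mask is not None and not mask[i]:
            continue
        if dev[i] > sd[i]:
            total += (dev[i] - sd[i]) * dt
            count += 1
    if count == 0:
        return 0.0
    if normalization == "outside_samples":
        return total / (count * dt)
    return total / window_s


def autocorr_loop(x: np.ndarray, k0: int, k1: int) -> float:
    """Naive O(n^2) biased normalized autocorrelation peak over [k0, k1]."""
    denom = sum(v * v for v in x)
    best = -np.inf
    for k in range(k0, k1 + 1):
        s = sum(x[t] * x[t + k] for t in range(len(x) - k))
        best = max(best, s / denom)
    return min(max(best, 0.0), 1.0)


def pearson_loop(a: np.ndarray, b: np.ndarray) -> float:
    am, bm = a.mean(), b.mean()
    num = sum((x - am) * (y - bm) for x, y in zip(a, b))
    da = sum((x - am) ** 2 for x in a)
    db = sum((y - bm) ** 2 for y in b)
    return num / np.sqrt(da * db)


def skewness_loop(v: np.ndarray) -> float:
    """Adjusted Fisher-Pearson skewness from the raw moment formula."""
    n = len(v)
    m = v.mean()
    m2 = ((v - m) ** 2).mean()
    m3 = ((v - m) ** 3).mean()
    g1 = m3 / m2 ** 1.5
    return g1 * np.sqrt(n * (n - 1)) / (n - 2)


def bouts_loop(speed: np.ndarray, dt: float, frac: float):
    """Run-length bout extraction: (intervals, durations, movement_pct)."""
    thr = frac * max(speed)
    above = [s > thr for s in speed]
    intervals = []
    i = 0
    while i < len(above):
        if above[i]:
            j = i
            while j + 1 < len(above) and above[j + 1]:
                j += 1
            intervals.append((i * dt, (j + 1) * dt))
            i = j + 1
        else:
            i += 1
    durations = [b - a for a, b in intervals]
    movement_pct = 100.0 * sum(above) / len(above)
    return intervals, durations, movement_pct


def despike_loop(z: np.ndarray, t_ms: np.ndarray, vmax: float,
                 valid: np.ndarray) -> np.ndarray:
    """Causal scan: drop the later sample of any too-fast jump."""
    removed = np.zeros(len(z), dtype=bool)
    survivor = None
    for k in range(len(z)):
        if not valid[k]:
            continue
        if survivor is None:
            survivor = k
            continue
        rate = abs(z[k] - z[survivor]) / ((t_ms[k] - t_ms[survivor]) / 1000.0)
        if rate > vmax:
            removed[k] = True
        else:
            survivor = k
    return removed
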