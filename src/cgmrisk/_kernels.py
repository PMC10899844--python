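"""Numba kernels for trailing-window statistics and lookahead labeling.

Each anchor's statistics are accumulated in a single left-to-right pass over
the readings in its window, matching the summation order of a naive loop, so
results are bit-identical to a straightforward reference recomputation.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Output column order of window_stats (one row per anchor).
STAT_COLUMNS = [
    "n_readings",
    "mean_glucose",
    "sd_glucose",
    "frac_time_low",
    "frac_time_high",
    "frac_below_54",
    "largest_increase",
    "largest_decrease",
    "max_consec_inc",
    "max_consec_dec",
]


@njit(cache=True)
def window_stats(
    times_s, glucose, anchor_idx, duration_s, low, high, very_low
):  # pragma: no cover - exercised via build_features
    n_anchors = anchor_idx.shape[0]
    out = np.full((n_anchors, 10), np.nan)
    left = 0
    for k in range(n_anchors):
        i = anchor_idx[k]
        bound = times_s[i] - duration_s  # window is (anchor - d, anchor]
        while times_s[left] <= bound:
            left += 1
        count = i - left + 1
        s = 0.0
        ss = 0.0
        n_low = 0
        n_high = 0
        n_vlow = 0
        max_inc = 0.0
        max_dec = 0.0
        run_inc = 0
        run_dec = 0
        best_inc = 0
        best_dec = 0
        prev = 0.0
        for j in range(left, i + 1):
            g = glucose[j]
            s += g
            ss += g * g
            if g < low:
                n_low += 1
            if g > high:
                n_high += 1
            if g < very_low:
                n_vlow += 1
            if j > left:
                d = g - prev
                if d > 0.0:
                    run_inc += 1
                    run_dec = 0
                    if d > max_inc:
                        max_inc = d
                elif d < 0.0:
                    run_dec += 1
                    run_inc = 0
                    if -d > max_dec:
                        max_dec = -d
                else:
                    run_inc = 0
                    run_dec = 0
                if run_inc > best_inc:
                    best_inc = run_inc
                if run_dec > best_dec:
                    best_dec = run_dec
            prev = g
        mean = s / count
        out[k, 0] = count
        out[k, 1] = mean
        out[k, 3] = n_low / count
        out[k, 4] = n_high / count
        out[k, 5] = n_vlow / count
        if count >= 2:
            var = ss / count - mean * mean
            if var < 0.0:
                var = 0.0
            out[k, 2] = np.sqrt(var)
            out[k, 6] = max_inc
            out[k, 7] = max_dec
            out[k, 8] = best_inc
            out[k, 9] = best_dec
    return out


@njit(cache=True)
def lookahead_extrema(times_s, glucose, anchor_idx, horizon_s):  # pragma: no cover
    """Per anchor: (count, min, max) of readings in (anchor, anchor + horizon]."""
    n_anchors = anchor_idx.shape[0]
    n = times_s.shape[0]
    out = np.full((n_anchors, 3), np.nan)
    for k in range(n_anchors):
        i = anchor_idx[k]
        bound = times_s[i] + horizon_s
        j = i + 1
        cnt = 0
        gmin = np.inf
        gmax = -np.inf
        while j < n and times_s[j] <= bound:
            g = glucose[j]
            if g < gmin:
                gmin = g
            if g > gmax:
                gmax = g
            cnt += 1
            j += 1
        out[k, 0] = cnt
        if cnt > 0:
            out[k, 1] = gmin
            out[k, 2] = gmax
    return out
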