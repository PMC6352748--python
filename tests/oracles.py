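"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's vectorized/scanning code paths:
ramps are enumerated by exhaustive window checks, statistics come from
numpy.polyfit / numpy.corrcoef, and the moving median sorts every window.
"""

from __future__ import annotations

import numpy as np


def brute_median_baseline(values, window):
    """Per-index sorted-median with symmetric truncation at the edges."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        k = min(half, i, n - 1 - i)
        win = sorted(values[i - k : i + k + 1])
        m = len(win)
        out[i] = win[m // 2] if m % 2 else 0.5 * (win[m // 2 - 1] + win[m // 2])
    return out


def _valid_step(values, gap_after, j, direction, threshold):
    """Step j -> j+1 continues a run in the given direction."""
    if gap_after[j]:
        return False
    return (values[j + 1] - values[j]) * direction > threshold


def brute_ramps(values, gap_after, min_len, threshold):
    """All maximal monotone runs, by per-start extension (O(N²) worst case).

    For every start index and direction the run is extended step by step as
    far as it stays valid; it is recorded when it reaches ``min_len`` and is
    not preceded by a valid step (maximality on the left; maximality on the
    right holds because extension stops only at an invalid step).
    Returns a set of (start, length, direction) tuples.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    found = set()
    for start in range(n - 1):
        for direction in (+1, -1):
            if start > 0 and _valid_step(values, gap_after, start - 1, direction, threshold):
                continue  # extendable left: not maximal
            end = start
            while end < n - 1 and _valid_step(values, gap_after, end, direction, threshold):
                end += 1
            length = end - start + 1
            if length >= min_len:
                found.add((start, length, direction))
    return found


def brute_sequences(sap_vals, pi_vals, gap_after, n, r_min, delay,
                    sap_threshold=0.0):
    """Brute-force sequence scan at one delay.

    Returns (n_evaluable, accepted) where accepted maps
    (start, length, direction) -> (slope, r) computed with polyfit/corrcoef.
    """
    sap_vals = np.asarray(sap_vals, dtype=float)
    pi_vals = np.asarray(pi_vals, dtype=float)
    ramps = sorted(brute_ramps(sap_vals, gap_after, n, sap_threshold))
    n_total = len(pi_vals)
    n_eval = 0
    accepted = {}
    for (start, length, direction) in ramps:
        p0 = start + delay
        if p0 + length > n_total:
            continue
        if length > 1 and any(gap_after[p0 : p0 + length - 1]):
            continue
        n_eval += 1
        x = sap_vals[start : start + length]
        y = pi_vals[p0 : p0 + length]
        if np.ptp(y) == 0:
            continue
        r = np.corrcoef(x, y)[0, 1]
        slope = np.polyfit(x, y, 1)[0]
        if r >= r_min and slope > 0:
            accepted[(start, length, direction)] = (slope, r)
    return n_eval, accepted
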