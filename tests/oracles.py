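"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as a direct, slow transcription of the rule being
checked, deliberately sharing no code with the package.
"""

import math

import numpy as np


def scan_detect(env, baseline_mean, baseline_sd, threshold_sd, min_duration_s,
                merge_gap_s, immobile_mask, fs):
    """Threshold-scan SWR oracle: mask -> runs -> merge -> duration filter.

    Returns a list of (start_idx, end_idx) half-open supra-threshold runs
    that survive; start_idx is the detection trigger.
    """
    thr = baseline_mean + threshold_sd * baseline_sd
    above = [bool(e > thr and m) for e, m in zip(env, immobile_mask)]
    runs = []
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            runs.append([i, j + 1])
            i = j + 1
        else:
            i += 1
    merged = []
    for run in runs:
        if merged and run[0] - merged[-1][1] < merge_gap_s * fs:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    return [tuple(r) for r in merged if r[1] - r[0] >= min_duration_s * fs]


def scan_immobility(t, v, threshold, qualify_s):
    """Frame-scan immobility oracle returning [start+qualify, end) intervals."""
    out = []
    i = 0
    n = len(v)
    while i < n:
        if v[i] < threshold:
            j = i
            while j + 1 < n and v[j + 1] < threshold:
                j += 1
            end = t[j + 1] if j + 1 < n else t[-1] + (t[-1] - t[-2])
            if end - t[i] >= qualify_s:
                out.append((t[i] + qualify_s, end))
            i = j + 1
        else:
            i += 1
    return out


def holm_sidak_max(p):
    """Closed-form step-down max formula, computed with explicit loops."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    for rank, idx in enumerate(order):
        best = 0.0
        for j in range(rank + 1):
            best = max(best, 1.0 - (1.0 - p[order[j]]) ** (m - j))
        adj[idx] = min(best, 1.0)
    return adj


def binom_tail(k, n, p):
    """P(X >= k) by direct pmf summation."""
    total = 0.0
    for i in range(k, n + 1):
        total += math.comb(n, i) * p**i * (1 - p) ** (n - i)
    return total


def scan_entrances(t, angle_deg, center_deg, width_deg, hysteresis_s):
    """Frame-scan shock-zone entrance counter with hysteresis."""
    def inside(a):
        d = (a - center_deg + 180.0) % 360.0 - 180.0
        return -width_deg / 2 <= d < width_deg / 2

    count = 0
    state = False
    first = 0
    while first < len(t) and inside(angle_deg[first]):  # placement, not entrance
        first += 1
    outside_since = None
    for i in range(first + 1, len(t)):
        now = inside(angle_deg[i])
        if state and not now:
            outside_since = t[i]
            state = False
        elif not state and now:
            if outside_since is None or t[i] - outside_since >= hysteresis_s or count == 0:
                count += 1
            state = True
    return count


def masked_mean_sd(values, mask):
    sel = [v for v, m in zip(values, mask) if m]
    mean = sum(sel) / len(sel)
    var = sum((v - mean) ** 2 for v in sel) / len(sel)
    return mean, math.sqrt(var)
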