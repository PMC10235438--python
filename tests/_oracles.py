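"""Independent brute-force oracles used by the test suite.

Everything here is written with plain Python loops directly from the
documented measurement definitions, deliberately sharing no code with the
package implementation it checks.
"""

from __future__ import annotations

import numpy as np


def brute_force_detect(v, dt, window, thr=20.0, peak_floor=-10.0,
                       onset=None, onset_blank_ms=5.0):
    """Derivative-scan AP detection, re-derived from the stated definition."""
    v = list(map(float, v))
    n = len(v)
    dt_ms = dt * 1e3
    d = [0.0] * n
    for i in range(1, n - 1):
        d[i] = (v[i + 1] - v[i - 1]) / (2.0 * dt_ms)
    d[0] = (v[1] - v[0]) / dt_ms
    d[-1] = (v[-1] - v[-2]) / dt_ms
    i_lo = int(round(window[0] / dt))
    i_hi = min(int(round(window[1] / dt)), n)
    out = []
    i = max(i_lo, 1)
    while i < i_hi:
        if d[i] >= thr and d[i - 1] < thr:
            j = i
            while j < n and d[j] >= 0.0:
                j += 1
            if j >= n:
                break
            p = i
            for k in range(i, j + 1):
                if v[k] > v[p]:
                    p = k
            t_thr = i * dt
            blanked = (onset is not None
                       and onset <= t_thr <= onset + onset_blank_ms * 1e-3)
            if v[p] >= peak_floor and not blanked:
                out.append((i, p))
            i = j + 1
        else:
            i += 1
    return out


def brute_force_bh(p):
    """Benjamini–Hochberg step-up by direct definition."""
    p = list(map(float, p))
    m = len(p)
    order = sorted(range(m), key=lambda k: p[k])
    adj = [None] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        k = order[rank - 1]
        val = min(prev, p[k] * m / rank, 1.0)
        adj[k] = val
        prev = val
    return adj


def brute_force_holm(p, sidak=False):
    """Holm step-down (Bonferroni or Šidák flavour) by direct definition."""
    p = list(map(float, p))
    m = len(p)
    order = sorted(range(m), key=lambda k: p[k])
    adj = [None] * m
    running = 0.0
    for rank, k in enumerate(order):
        mult = m - rank
        val = 1.0 - (1.0 - p[k]) ** mult if sidak else mult * p[k]
        running = max(running, min(1.0, val))
        adj[k] = running
    return adj


def brute_force_bonferroni(p):
    return [min(1.0, len(p) * float(x)) for x in p]


def brute_force_ap_features(v, dt, i_thr, i_peak, thr=20.0):
    """Threshold voltage, amplitude and half width by direct array scans."""
    v = np.asarray(v, float)
    dt_ms = dt * 1e3
    d_prev = (v[i_thr] - v[i_thr - 2]) / (2 * dt_ms)
    d_here = (v[i_thr + 1] - v[i_thr - 1]) / (2 * dt_ms)
    frac = (thr - d_prev) / (d_here - d_prev)
    thr_v = v[i_thr - 1] + frac * (v[i_thr] - v[i_thr - 1])
    amp = v[i_peak] - thr_v
    level = thr_v + amp / 2
    k = i_peak
    while v[k - 1] > level:
        k -= 1
    t_up = (k - 1 + (level - v[k - 1]) / (v[k] - v[k - 1])) * dt
    k = i_peak
    while v[k + 1] > level:
        k += 1
    t_down = (k + (level - v[k]) / (v[k + 1] - v[k])) * dt
    return float(thr_v), float(amp), float((t_down - t_up) * 1e3)
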