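"""Action-potential detection and current-clamp excitability measures.

AP threshold is the point where the first derivative of the voltage trace
exceeds a slope criterion (default 20 mV/ms); every other waveform feature —
amplitude, half width, AHP amplitude and AHP delay — is measured relative to
that threshold.  Detection follows a strict, reproducible scan:

1. d[i] = (v[i+1] − v[i−1]) / (2·dt) in mV/ms (one-sided at the ends).
2. A candidate starts at each upward crossing of the slope criterion
   (d[i] ≥ thr and d[i−1] < thr) inside the analysis window.
3. From the crossing, advance to the first sample j where d[j] < 0; the AP
   peak is the voltage maximum over [i, j].  The upstroke may complete past
   the window end (an AP initiated at the edge still counts); candidates
   truncated by the end of the trace are dropped.
4. The candidate is accepted iff the peak reaches ``peak_floor`` (rejects
   subthreshold noise blips), its threshold lies inside the window
   (spontaneous APs excluded), and it does not coincide with the current
   injection onset (within ``onset_blank`` ms).  Scanning resumes after j,
   so detections never overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trace_io import SweepSeries, Trace

__all__ = [
    "APFeature",
    "ExcitabilityResult",
    "detect_aps",
    "ap_features",
    "rheobase_analysis",
    "io_curve_from_held",
    "accommodation_index",
]


@dataclass(frozen=True)
class APFeature:
    """Waveform features of one action potential (times s, voltages mV, widths ms)."""

    threshold_time: float
    threshold_V: float
    peak_time: float
    peak_V: float
    half_width: float
    ahp_V: float | None = None
    ahp_delay: float | None = None  # ms, trough time minus threshold time
    ahp_flag: str | None = None

    @property
    def amplitude(self) -> float:
        return self.peak_V - self.threshold_V

    @property
    def ahp_amplitude(self) -> float | None:
        return None if self.ahp_V is None else self.threshold_V - self.ahp_V


@dataclass(frozen=True)
class ExcitabilityResult:
    """Per-cell excitability summary from a current-step family."""

    rheobase: float | None           # pA; None if no sweep spikes
    io_curve: dict[float, int]       # injection pA -> AP count
    first_ap: APFeature | None
    accommodation_index: float | None
    flags: tuple[str, ...] = ()


def _derivative(v: np.ndarray, dt: float) -> np.ndarray:
    """First derivative in mV/ms, central differences (one-sided at ends)."""
    d = np.empty_like(v)
    dt_ms = dt * 1e3
    d[1:-1] = (v[2:] - v[:-2]) / (2.0 * dt_ms)
    d[0] = (v[1] - v[0]) / dt_ms
    d[-1] = (v[-1] - v[-2]) / dt_ms
    return d


def detect_aps(
    trace: Trace,
    window: tuple[float, float] | None = None,
    dvdt_threshold: float = 20.0,
    peak_floor: float = -10.0,
    onset_blank: float = 5.0,
    onset: float | None = None,
) -> list[tuple[int, int]]:
    """Detect APs; returns (threshold sample, peak sample) index pairs.

    ``window`` is the analysis interval in seconds (default: whole trace);
    ``onset`` is the current-injection onset used for the coincidence
    exclusion (``onset_blank`` ms).  See the module docstring for the exact
    scan; the brute-force property tests re-derive it independently.
    """
    if trace.role != "membrane_voltage":
        raise TypeError("detect_aps expects a membrane-voltage trace")
    v = trace.samples
    if window is None:
        window = (0.0, trace.duration)
    if window[0] < 0 or window[1] > trace.duration + trace.dt / 2:
        raise IndexError(f"window {window} outside trace of duration {trace.duration}")
    i_lo, i_hi = trace.index_at(window[0]), min(trace.index_at(window[1]), v.size)
    if not i_lo < i_hi:
        raise IndexError(f"empty analysis window {window}")
    d = _derivative(v, trace.dt)
    blank_hi = None
    if onset is not None:
        blank_hi = onset + onset_blank * 1e-3

    out: list[tuple[int, int]] = []
    i = max(i_lo, 1)
    while i < i_hi:
        if d[i] >= dvdt_threshold and d[i - 1] < dvdt_threshold:
            j = i
            while j < v.size and d[j] >= 0.0:
                j += 1
            if j >= v.size:
                break  # upstroke truncated by end of trace
            p = i + int(np.argmax(v[i:j + 1]))
            t_thr = i * trace.dt
            blanked = (blank_hi is not None and onset is not None
                       and onset <= t_thr <= blank_hi)
            if v[p] >= peak_floor and not blanked:
                out.append((i, p))
            i = j + 1
        else:
            i += 1
    return out


def _interp_crossing(x0, x1, y0, y1, level):
    """x where the segment (x0,y0)-(x1,y1) crosses y=level."""
    return x0 + (level - y0) / (y1 - y0) * (x1 - x0)


def ap_features(
    trace: Trace,
    detection: tuple[int, int],
    search_end: int | None = None,
    dvdt_threshold: float = 20.0,
    ahp_reference: str = "threshold",
) -> APFeature:
    """Measure one detected AP.

    Threshold voltage/time are refined by linear interpolation between the
    samples bracketing the slope-criterion crossing; the half width is the
    interpolated width at threshold + amplitude/2.  The AHP trough is the
    minimum between the peak and ``search_end`` (the next AP's threshold
    sample, or the end of the analysis window); if the minimum sits on the
    boundary there is no trough and the AHP fields are absent, flagged.
    ``ahp_reference`` selects the AHP-delay origin: the threshold time
    (default, matching "relative to this threshold") or the peak time.
    """
    i, p = detection
    v = trace.samples
    d = _derivative(v, trace.dt)
    if search_end is None:
        search_end = v.size
    # sub-sample threshold crossing
    if i >= 1 and d[i] != d[i - 1]:
        frac = (dvdt_threshold - d[i - 1]) / (d[i] - d[i - 1])
    else:
        frac = 0.0
    threshold_time = (i - 1 + frac) * trace.dt
    threshold_V = v[i - 1] + frac * (v[i] - v[i - 1]) if i >= 1 else v[i]
    peak_V = float(v[p])
    amplitude = peak_V - threshold_V
    if amplitude <= 0:
        raise ValueError("invalid detection: peak below threshold")

    half_level = threshold_V + amplitude / 2.0
    # last upward crossing before the peak, first downward after
    k = p
    while k > 0 and v[k - 1] > half_level:
        k -= 1
    t_up = _interp_crossing((k - 1) * trace.dt, k * trace.dt, v[k - 1], v[k], half_level)
    k = p
    while k + 1 < v.size and v[k + 1] > half_level:
        k += 1
    if k + 1 >= v.size:
        t_down = k * trace.dt  # falling flank truncated; degrade gracefully
    else:
        t_down = _interp_crossing(k * trace.dt, (k + 1) * trace.dt, v[k], v[k + 1], half_level)
    half_width = (t_down - t_up) * 1e3

    ahp_V = ahp_delay = None
    flag = None
    seg = v[p:search_end]
    if seg.size >= 3:
        m = p + int(np.argmin(seg))
        if m in (p, search_end - 1):
            flag = "no_trough_before_window_end"
        else:
            ahp_V = float(v[m])
            origin = threshold_time if ahp_reference == "threshold" else p * trace.dt
            ahp_delay = (m * trace.dt - origin) * 1e3
    else:
        flag = "no_trough_before_window_end"
    return APFeature(threshold_time=float(threshold_time), threshold_V=float(threshold_V),
                     peak_time=p * trace.dt, peak_V=peak_V, half_width=float(half_width),
                     ahp_V=ahp_V, ahp_delay=ahp_delay, ahp_flag=flag)


def accommodation_index(
    ap_threshold_times: np.ndarray,
    min_aps: int = 6,
    direction: str = "last_over_first",
) -> float | None:
    """Spike-frequency accommodation: last inter-AP interval over the first.

    Returns ``(t_N − t_{N−1}) / (t_2 − t_1)`` for a train of N ≥ ``min_aps``
    APs (values > 1 mean slowing); ``direction="first_over_last"`` returns
    the reciprocal.  None when the train is too short.
    """
    t = np.asarray(ap_threshold_times, dtype=float)
    if t.size < min_aps:
        return None
    ratio = (t[-1] - t[-2]) / (t[1] - t[0])
    if direction == "first_over_last":
        ratio = 1.0 / ratio
    elif direction != "last_over_first":
        raise ValueError(f"unknown direction {direction!r}")
    return float(ratio)


def rheobase_analysis(
    series: SweepSeries,
    dvdt_threshold: float = 20.0,
    peak_floor: float = -10.0,
    onset_blank: float = 5.0,
    min_aps: int = 6,
) -> ExcitabilityResult:
    """Rheobase, I/O curve and first-AP features from a current-step family.

    Rheobase is the lowest step level whose sweep yields at least one valid
    detection within the injection window; the first AP of that sweep
    provides the waveform features.  The accommodation index is computed on
    the lowest step evoking at least ``min_aps`` APs.
    """
    prot = series.protocol
    window = (prot.step_onset, prot.step_offset)
    io: dict[float, int] = {}
    detections = {}
    for level, sweep in zip(prot.step_levels, series.sweeps):
        det = detect_aps(sweep, window=window, dvdt_threshold=dvdt_threshold,
                         peak_floor=peak_floor, onset_blank=onset_blank,
                         onset=prot.step_onset)
        io[float(level)] = len(det)
        detections[float(level)] = det

    spiking = [lvl for lvl in io if io[lvl] >= 1]
    flags: list[str] = []
    rheobase = first_ap = None
    if spiking:
        rheobase = min(spiking)
        sweep = series.sweep_for_level(rheobase)
        det = detections[rheobase]
        nxt = det[1][0] if len(det) > 1 else sweep.index_at(prot.step_offset)
        first_ap = ap_features(sweep, det[0], search_end=nxt,
                               dvdt_threshold=dvdt_threshold)
    else:
        flags.append("no_spiking_sweep")

    acc = None
    trains = sorted(lvl for lvl in io if io[lvl] >= min_aps)
    if trains:
        sweep = series.sweep_for_level(trains[0])
        times = np.array([i * sweep.dt for i, _ in detections[trains[0]]])
        acc = accommodation_index(times, min_aps=min_aps)
    return ExcitabilityResult(rheobase=rheobase, io_curve=io, first_ap=first_ap,
                              accommodation_index=acc, flags=tuple(flags))


def io_curve_from_held(
    series: SweepSeries,
    held_V: float = -70.0,
    tolerance: float = 3.0,
    dvdt_threshold: float = 20.0,
    peak_floor: float = -10.0,
    onset_blank: float = 5.0,
) -> tuple[dict[float, int], dict[float, str]]:
    """AP counts per injection step from a holding potential near ``held_V``.

    The pre-step baseline of each sweep must sit within ``tolerance`` mV of
    ``held_V``; drifted sweeps are excluded from the curve and reported in
    the flags mapping instead.
    """
    prot = series.protocol
    curve: dict[float, int] = {}
    flags: dict[float, str] = {}
    for level, sweep in zip(prot.step_levels, series.sweeps):
        base = float(sweep.samples[:sweep.index_at(prot.step_onset)].mean())
        if abs(base - held_V) > tolerance:
            flags[float(level)] = f"baseline {base:.1f} mV deviates from {held_V} mV"
            continue
        det = detect_aps(sweep, window=(prot.step_onset, prot.step_offset),
                         dvdt_threshold=dvdt_threshold, peak_floor=peak_floor,
                         onset_blank=onset_blank, onset=prot.step_onset)
        curve[float(level)] = len(det)
    return curve, flags
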