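"""Miniature EPSC detection and statistics.

Events are inward (negative) deflections on a TTX voltage-clamp baseline.
Detection: the trace is lightly smoothed, a running median baseline is
subtracted, deflection peaks beyond an amplitude threshold are located, and
each candidate's onset is the last baseline crossing before its peak;
candidates must satisfy an onset-to-peak rise-time bound.  Following the
summation rule, events whose onset falls less than 10 ms after the previous
event are kept for frequency/interval statistics but excluded from
amplitude statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .trace_io import Trace

__all__ = ["MiniEvent", "MiniSummary", "detect_minis", "mini_summary"]

SUMMATION_GAP = 0.010  # s; closer events summate → amplitude excluded
SUFFICIENT_EVENTS = 200


@dataclass(frozen=True)
class MiniEvent:
    onset: float                  # s
    peak: float                   # s
    amplitude: float              # pA, baseline-to-peak magnitude
    preceding_interval: float | None  # s since previous event onset
    amplitude_included: bool

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")


@dataclass(frozen=True)
class MiniSummary:
    n_events: int
    frequency: float              # Hz, over ALL events
    mean_interval: float | None   # s
    median_interval: float | None
    amplitude_mean: float | None  # over amplitude-included events only
    amplitude_median: float | None
    amplitude_sd: float | None
    n_amplitude: int
    sufficient: bool              # n_events >= 200


def _running_baseline(x: np.ndarray, dt: float, window_s: float = 0.05,
                      stride_s: float = 0.001) -> np.ndarray:
    """Trailing-window running median, computed on a decimated grid and
    linearly interpolated back to the full sampling grid."""
    stride = max(1, int(round(stride_s / dt)))
    idx = np.arange(0, x.size, stride)
    coarse = x[idx]
    k = max(1, int(round(window_s / dt / stride)))
    pad = np.concatenate([np.full(k - 1, coarse[0]), coarse])
    windows = np.lib.stride_tricks.sliding_window_view(pad, k)
    med = np.median(windows, axis=1)
    return np.interp(np.arange(x.size), idx, med)


def detect_minis(
    trace: Trace,
    threshold: float = 5.0,
    rise_bounds: tuple[float, float] = (0.3, 5.0),
    smooth_ms: float = 0.5,
    baseline_window_ms: float = 50.0,
    min_separation_ms: float = 2.0,
) -> list[MiniEvent]:
    """Detect miniature EPSCs on a voltage-clamp current trace.

    ``threshold`` (pA) is the minimum baseline-to-peak deflection;
    ``rise_bounds`` (ms) bound the onset-to-peak time.  Returns events
    sorted by onset with ``preceding_interval`` and the 10 ms
    ``amplitude_included`` rule populated.
    """
    if trace.role != "membrane_current":
        raise TypeError("detect_minis expects a membrane-current trace")
    x = trace.samples
    dt = trace.dt
    k = max(1, int(round(smooth_ms * 1e-3 / dt)))
    smooth = np.convolve(x, np.ones(k) / k, mode="same")
    baseline = _running_baseline(smooth, dt, window_s=baseline_window_ms * 1e-3)
    defl = baseline - smooth  # positive = inward deflection

    distance = max(1, int(round(min_separation_ms * 1e-3 / dt)))
    # prominence on top of the absolute height rejects secondary ripples on
    # the decay of a large event while keeping genuinely stacked events
    peaks, _ = find_peaks(defl, height=threshold, prominence=threshold,
                          distance=distance)

    events: list[MiniEvent] = []
    prev_onset: float | None = None
    prev_peak: int | None = None
    lo, hi = rise_bounds
    lookback = max(1, int(round(10e-3 / dt)))
    for p in peaks:
        # onset: last baseline crossing before the peak; for an event
        # stacked on the decay of the previous one (walk-back reaches past
        # that event's peak) the inter-event dip serves as the onset instead
        i = p
        lim = max(0, p - lookback)
        while i > lim and defl[i - 1] > 0:
            i -= 1
        crossing_found = i == 0 or defl[i - 1] <= 0
        if prev_peak is not None and prev_peak < p and (
                not crossing_found or i <= prev_peak):
            i = prev_peak + int(np.argmin(defl[prev_peak:p]))
        rise_ms = (p - i) * dt * 1e3
        if not lo <= rise_ms <= hi:
            continue
        prev_peak = p
        onset = i * dt
        interval = None if prev_onset is None else onset - prev_onset
        events.append(MiniEvent(
            onset=onset, peak=p * dt, amplitude=float(defl[p]),
            preceding_interval=interval,
            amplitude_included=interval is None or interval >= SUMMATION_GAP,
        ))
        prev_onset = onset
    return events


def mini_summary(events: list[MiniEvent], duration: float) -> MiniSummary:
    """Summarise a detected event list.

    Frequency and inter-event intervals use ALL events; amplitude statistics
    use only events passing the 10 ms summation rule.  ``sufficient`` marks
    recordings reaching the 200-event requirement.
    """
    n = len(events)
    onsets = np.array([e.onset for e in events])
    if n >= 2:
        freq = (n - 1) / (onsets[-1] - onsets[0])
        iei = np.diff(onsets)
        mean_iei, med_iei = float(iei.mean()), float(np.median(iei))
    else:
        freq = n / duration if duration > 0 else 0.0
        mean_iei = med_iei = None
    amps = np.array([e.amplitude for e in events if e.amplitude_included])
    return MiniSummary(
        n_events=n, frequency=float(freq),
        mean_interval=mean_iei, median_interval=med_iei,
        amplitude_mean=float(amps.mean()) if amps.size else None,
        amplitude_median=float(np.median(amps)) if amps.size else None,
        amplitude_sd=float(amps.std(ddof=1)) if amps.size > 1 else None,
        n_amplitude=int(amps.size),
        sufficient=n >= SUFFICIENT_EVENTS,
    )
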