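"""Multi-ROI calcium-field generator with shared synchronous transients."""

from __future__ import annotations

import numpy as np

from ..fluorescence import RoiTraceSet
from ..trace_io import Trace
from .params import GroundTruth

__all__ = ["simulate_calcium_field"]

CALCIUM_TAU = 1.0  # s, indicator decay time constant


def _add_transient(f: np.ndarray, t_grid: np.ndarray, t0: float, amp: float) -> None:
    """Add an instant-rise, exponential-decay transient (peak = amp) in place."""
    m = t_grid >= t0
    f[m] += amp * np.exp(-(t_grid[m] - t0) / CALCIUM_TAU)


def simulate_calcium_field(
    n_rois: int = 20,
    event_times: np.ndarray | None = None,
    event_amp: float = 0.3,
    jitter_sd: float = 0.1,
    noise_sd: float = 2.0,
    bic_peak: float = 1.0,
    fps: float = 2.0,
    duration: float = 600.0,
    bic_duration: float = 60.0,
    baseline_mean: float = 100.0,
    background: float = 10.0,
    seed: int = 0,
) -> tuple[RoiTraceSet, GroundTruth]:
    """Simulate an imaging field of ~15–30 somata with synchronous transients.

    Each ROI carries every shared event as a calcium-kernel transient with
    per-cell amplitude scaling and onset jitter (sd ``jitter_sd`` s) on an
    ROI-specific baseline; ``event_amp`` and ``bic_peak`` are in ΔF/F units
    of the ROI baseline.  After ``duration`` s a bicuculline segment begins
    (the marker), containing one reference transient whose population-mean
    ΔF/F peak equals ``bic_peak``.  Ground truth records the *realised*
    noise-free population-mean peak of every event, plus whether it meets
    the 1/10-of-reference criterion.
    """
    if not 15 <= n_rois <= 30:
        raise ValueError("n_rois outside the 15-30 field size range")
    n = int(round((duration + bic_duration) * fps))
    if n < 10:
        raise ValueError("fps * duration too small: fewer than 10 samples")
    rng = np.random.default_rng(seed)
    dt = 1.0 / fps
    t_grid = np.arange(n) * dt

    if event_times is None:
        # sparse events in the unstimulated segment, clear of the baseline
        # estimation window and of each other
        times: list[float] = []
        while len(times) < 4:
            c = rng.uniform(90.0, duration - 30.0)
            if all(abs(c - x) > 20.0 for x in times):
                times.append(c)
        event_times = np.sort(times)
    event_times = np.round(np.sort(np.asarray(event_times, float)) * fps) / fps
    if np.any(np.diff(event_times) <= 5.0):
        raise ValueError("synchronous events must be separated by more than 5 s")
    if event_times.size and event_times[-1] >= duration:
        raise ValueError("event_times must lie in the unstimulated segment")

    bic_marker = int(round(duration * fps))
    t_bic = np.round((duration + 5.0) * fps) / fps

    baselines = baseline_mean * rng.uniform(0.7, 1.3, size=n_rois)
    scales = np.clip(rng.normal(1.0, 0.2, size=(n_rois, event_times.size)), 0.2, None)
    jitters = rng.normal(0.0, jitter_sd, size=(n_rois, event_times.size))

    clean = np.empty((n_rois, n))
    traces = []
    for j in range(n_rois):
        f = np.zeros(n)
        for k, t0 in enumerate(event_times):
            _add_transient(f, t_grid, t0 + jitters[j, k], event_amp * scales[j, k])
        _add_transient(f, t_grid, t_bic, bic_peak)
        clean[j] = f  # per-ROI noise-free dF/F
        raw = baselines[j] * (1.0 + f) + background
        if noise_sd > 0:
            raw = raw + rng.normal(0.0, noise_sd, size=n)
        traces.append(Trace(raw, dt=dt, units="AU", role="fluorescence"))

    pop = clean.mean(axis=0)
    half = int(round(2.0 * fps))
    realised = np.array([
        pop[max(0, int(round(e * fps)) - half):int(round(e * fps)) + half + 1].max()
        for e in event_times
    ])
    bic_realised = float(pop[bic_marker:].max())
    truth = GroundTruth(
        calcium_event_times=event_times,
        calcium_event_amplitudes=realised,
        calcium_supra_criterion=realised >= 0.1 * bic_realised,
        bic_reference_peak=bic_realised,
        extras={"nominal_event_amp": event_amp, "nominal_bic_peak": bic_peak},
    )
    return RoiTraceSet(tuple(traces), background=background, bic_marker=bic_marker), truth
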