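"""Miniature-EPSC train generator: Poisson events on a noisy baseline."""

from __future__ import annotations

import numpy as np

from ..trace_io import Trace
from .params import GroundTruth

__all__ = ["simulate_mepsc", "biexp_kernel_peak"]


def biexp_kernel_peak(tau_rise: float, tau_decay: float) -> tuple[float, float]:
    """Peak time and peak value of exp(-t/τd) − exp(-t/τr), τr < τd."""
    t_pk = tau_rise * tau_decay / (tau_decay - tau_rise) * np.log(tau_decay / tau_rise)
    return t_pk, np.exp(-t_pk / tau_decay) - np.exp(-t_pk / tau_rise)


def simulate_mepsc(
    rate: float = 1.0,
    amp_dist: tuple[float, float] = (20.0, 5.0),
    kinetics: tuple[float, float] = (0.5, 5.0),
    duration: float = 300.0,
    noise_sd: float = 2.0,
    seed: int = 0,
    dt: float = 5e-5,
    event_times: np.ndarray | None = None,
) -> tuple[Trace, GroundTruth]:
    """Simulate a voltage-clamp trace of miniature EPSCs.

    Events arrive as a homogeneous Poisson process at ``rate`` Hz (or at
    explicitly planted ``event_times``); each is a biexponential inward
    (negative) deflection with rise/decay time constants ``kinetics`` in
    ms, peak amplitude drawn from a normal ``amp_dist = (mean, sd)`` in pA
    (clipped at 2 pA), normalised so the waveform's peak equals the drawn
    amplitude exactly.  The baseline is 0 pA plus white Gaussian noise.
    Ground truth holds the exact onset times and amplitudes.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    tau_rise, tau_decay = kinetics
    if not tau_rise < tau_decay:
        raise ValueError("need tau_rise < tau_decay")
    rng = np.random.default_rng(seed)
    if event_times is not None:
        times = np.sort(np.asarray(event_times, float))
    else:
        # homogeneous Poisson process via exponential gaps
        ts = []
        t = rng.exponential(1.0 / rate)
        while t < duration:
            ts.append(t)
            t += rng.exponential(1.0 / rate)
        times = np.array(ts)
    amps = np.clip(rng.normal(amp_dist[0], amp_dist[1], size=times.size), 2.0, None)

    n = int(round(duration / dt))
    trace = np.zeros(n)
    _, k_peak = biexp_kernel_peak(tau_rise, tau_decay)
    span = int(round(10 * tau_decay * 1e-3 / dt))
    tk = np.arange(span) * dt * 1e3  # ms
    kernel = (np.exp(-tk / tau_decay) - np.exp(-tk / tau_rise)) / k_peak
    for t0, a in zip(times, amps):
        i0 = int(round(t0 / dt))
        seg = min(span, n - i0)
        if seg > 0:
            trace[i0:i0 + seg] -= a * kernel[:seg]
    if noise_sd > 0:
        trace += rng.normal(0.0, noise_sd, size=n)

    warning = None
    if rate * duration < 1.0:
        warning = "duration too short: fewer than one event expected"
    truth = GroundTruth(mepsc_times=times, mepsc_amplitudes=amps, warning=warning)
    return Trace(trace, dt=dt, units="pA", role="membrane_current",
                 lowpass_cutoff=2e3), truth
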