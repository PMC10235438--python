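"""Passive membrane properties: resting potential, input resistance, capacitance.

The amplifier-reported values the recordings relied on are recomputed here
from the sweeps themselves: resting potential as a clean-baseline mean,
input resistance as the Ohmic slope of steady-state voltage deflections
against hyperpolarizing current steps, and whole-cell capacitance as the
charge integral of the voltage-clamp test-pulse transient divided by the
step size.  "Stabilized" values across repeated test pulses are taken as
the median.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spike_features import detect_aps
from .trace_io import SweepSeries, Trace

__all__ = [
    "PassiveProperties",
    "resting_potential",
    "input_resistance",
    "capacitance_from_transient",
    "passive_from_test_pulses",
]


@dataclass(frozen=True)
class PassiveProperties:
    resting_V: float | None      # mV
    input_resistance: float | None  # MΩ
    capacitance: float | None    # pF
    access_resistance: float | None = None  # MΩ

    def __post_init__(self) -> None:
        if self.input_resistance is not None and self.input_resistance <= 0:
            raise ValueError("input_resistance must be positive")
        if self.capacitance is not None and self.capacitance <= 0:
            raise ValueError("capacitance must be positive")


def resting_potential(trace: Trace, baseline_window: tuple[float, float]) -> float:
    """Mean membrane voltage over an AP-free baseline window (mV).

    Raises if any AP is detected inside the window, directing the caller to
    a clean segment.
    """
    if detect_aps(trace, window=baseline_window):
        raise ValueError("APs detected in baseline window; choose a clean window")
    i0, i1 = (trace.index_at(t) for t in baseline_window)
    return float(trace.samples[i0:i1].mean())


def input_resistance(
    series: SweepSeries,
    ss_fraction: float = 0.2,
) -> tuple[float, dict[float, str]]:
    """Input resistance (MΩ) from subthreshold hyperpolarizing steps.

    ΔV is the steady-state deflection (mean over the last ``ss_fraction`` of
    the step) relative to the pre-step baseline; the resistance is the
    least-squares slope of ΔV against ΔI over all usable sweeps.
    Depolarizing or spiking sweeps are excluded automatically and reported
    in the returned flags mapping.
    """
    prot = series.protocol
    i_on, i_off = (series.sweeps[0].index_at(t) for t in (prot.step_onset, prot.step_offset))
    i_ss = i_off - max(2, int(round(ss_fraction * (i_off - i_on))))
    dv, di = [], []
    flags: dict[float, str] = {}
    for level, sweep in zip(prot.step_levels, series.sweeps):
        if level >= 0:
            flags[float(level)] = "not hyperpolarizing"
            continue
        if detect_aps(sweep, window=(prot.step_onset, prot.step_offset)):
            flags[float(level)] = "spiking sweep excluded"
            continue
        base = sweep.samples[:i_on].mean()
        dv.append(sweep.samples[i_ss:i_off].mean() - base)
        di.append(level)
    if len(dv) < 2:
        raise ValueError("need at least 2 usable hyperpolarizing sweeps")
    slope = np.polyfit(np.asarray(di), np.asarray(dv), 1)[0]  # mV/pA = GΩ
    return float(slope * 1e3), flags


def capacitance_from_transient(
    sweep: Trace,
    step_onset: float,
    delta_v: float,
    noise_window: tuple[float, float] | None = None,
    settle_ms: float = 1.0,
    max_ms: float = 50.0,
) -> float:
    """Whole-cell capacitance (pF) from a voltage-clamp test-pulse transient.

    ``C = ∫ (I − I_steady) dt / ΔV`` over the charging transient after the
    step.  The transient end is the first sample where |I − I_steady| stays
    below 3× the baseline noise sd for ``settle_ms``; raises if the
    transient has not settled within ``max_ms`` (clipped transient).
    """
    if sweep.role != "membrane_current":
        raise TypeError("capacitance needs a membrane-current sweep")
    if delta_v == 0:
        raise ValueError("delta_v must be nonzero")
    i_on = sweep.index_at(step_onset)
    if noise_window is None:
        noise_window = (0.0, step_onset)
    j0, j1 = (sweep.index_at(t) for t in noise_window)
    noise_sd = float(sweep.samples[j0:max(j1, j0 + 2)].std())

    i_max = min(sweep.n, i_on + sweep.index_at(max_ms * 1e-3))
    n_settle = max(1, sweep.index_at(settle_ms * 1e-3))
    # steady level from the tail of the search region
    steady = float(sweep.samples[i_max - n_settle:i_max].mean())
    resid = np.abs(sweep.samples[i_on:i_max] - steady)
    below = resid < max(3.0 * noise_sd, 1e-12)
    run = 0
    i_end = None
    for k, ok in enumerate(below):
        run = run + 1 if ok else 0
        if run >= n_settle:
            i_end = i_on + k - n_settle + 1
            break
    if i_end is None:
        raise ValueError("transient did not settle: clipped or window too short")
    charge = np.trapezoid(sweep.samples[i_on:i_on + (i_end - i_on) + n_settle] - steady,
                          dx=sweep.dt)  # pA*s
    return float(charge / delta_v * 1e3)  # pA*s/mV = nF -> pF


def passive_from_test_pulses(
    pulses: list[SweepSeries],
) -> PassiveProperties:
    """Median capacitance and access-resistance estimate across test pulses.

    Each series is a single-sweep voltage-clamp test step; the access
    resistance is estimated as ΔV over the peak transient current.
    """
    caps, ras = [], []
    for series in pulses:
        prot = series.protocol
        dv = float(prot.step_levels[0] - prot.holding)
        sweep = series.sweeps[0]
        caps.append(capacitance_from_transient(sweep, prot.step_onset, dv))
        i_on = sweep.index_at(prot.step_onset)
        base = sweep.samples[:i_on].mean()
        seg = sweep.samples[i_on:i_on + sweep.index_at(10e-3)] - base
        peak = seg[np.argmax(np.abs(seg))]
        ras.append(abs(dv / peak) * 1e3)  # mV/pA = GΩ -> MΩ
    return PassiveProperties(resting_V=None, input_resistance=None,
                             capacitance=float(np.median(caps)) if caps else None,
                             access_resistance=float(np.median(ras)) if ras else None)
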