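"""Current-clamp simulator: Hodgkin–Huxley-style single compartment.

The model carries fast Na and delayed-rectifier K conductances for the spike
waveform (so amplitude, half width and AHP are meaningful), plus leak, Kir,
HCN, A-type and an M-like adaptation conductance.  Integration is a
fixed-step explicit 4th-order Runge–Kutta scheme; the passive limit then has
a closed-form steady state (ΔV = ΔI / g_leak) that the tests check exactly.

Measurement noise is added to the *recorded* samples only, never to the
dynamics, so the spike ground truth (upward 0 mV crossings of the model
trajectory) is independent of the noise draw.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from ..trace_io import StepProtocol, SweepSeries, Trace
from .params import GroundTruth, NeuronParams, SimulationError

__all__ = [
    "simulate_current_clamp",
    "standard_current_clamp_protocol",
    "rheobase_dense_oracle",
    "hh_steady_gates",
]

MAX_DT = 25e-6  # s; explicit scheme is comfortably stable below this


def _vtrap(x: float, y: float) -> float:
    """x / (1 - exp(-x/y)) with the removable singularity at x=0 filled."""
    if abs(x / y) < 1e-6:
        return y * (1.0 - x / y / 2.0)
    return x / (1.0 - math.exp(-x / y))


@njit(cache=True, inline="always")
def _vtrap_nb(x, y):
    if abs(x / y) < 1e-6:
        return y * (1.0 - x / y / 2.0)
    return x / (1.0 - math.exp(-x / y))


def hh_steady_gates(v):
    """Steady-state (m, h, n) of the spike-generating conductances."""
    v = np.asarray(v, dtype=float)
    vt = np.vectorize(_vtrap)
    am = 0.1 * vt(v + 40.0, 10.0)
    bm = 4.0 * np.exp(-(v + 65.0) / 18.0)
    ah = 0.07 * np.exp(-(v + 65.0) / 20.0)
    bh = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
    an = 0.01 * vt(v + 55.0, 10.0)
    bn = 0.125 * np.exp(-(v + 65.0) / 80.0)
    return am / (am + bm), ah / (ah + bh), an / (an + bn)


@njit(cache=True, inline="always")
def _derivs(v, m, h, n, z, y, a, b, i_inj, p):
    # p: packed parameter vector, see _pack_params
    vna = v - p[24]  # Na kinetics voltage shift
    am = 0.1 * _vtrap_nb(vna + 40.0, 10.0)
    bm = 4.0 * math.exp(-(vna + 65.0) / 18.0)
    ah = 0.07 * math.exp(-(vna + 65.0) / 20.0)
    bh = 1.0 / (1.0 + math.exp(-(vna + 35.0) / 10.0))
    an = 0.01 * _vtrap_nb(v + 55.0, 10.0)
    bn = 0.125 * math.exp(-(v + 65.0) / 80.0)

    z_inf = 1.0 / (1.0 + math.exp(-(v + 35.0) / 10.0))
    y_inf = 1.0 / (1.0 + math.exp((v - p[13]) / p[14]))
    a_inf = 1.0 / (1.0 + math.exp(-(v - p[17]) / p[18]))
    b_inf = 1.0 / (1.0 + math.exp((v - p[20]) / p[21]))
    kir = 1.0 / (1.0 + math.exp((v - p[10]) / p[11]))

    i_mem = p[1] * (v - p[2])                       # leak
    i_mem += p[3] * m * m * m * h * (v - p[4])      # Na
    i_mem += p[5] * n * n * n * n * (v - p[6])      # K delayed rectifier
    i_mem += p[7] * z * (v - p[6])                  # adaptation
    i_mem += p[9] * kir * (v - p[6])                # Kir (instantaneous)
    i_mem += p[12] * y * (v - p[15])                # HCN
    i_mem += p[16] * a * b * (v - p[6])             # A-type

    dv = (i_inj - i_mem) / p[0]
    dm = am * (1.0 - m) - bm * m
    dh = ah * (1.0 - h) - bh * h
    dn = an * (1.0 - n) - bn * n
    dz = (z_inf - z) / p[8]
    dy = (y_inf - y) / p[19]
    da = (a_inf - a) / p[22]
    db = (b_inf - b) / p[23]
    return dv, dm, dh, dn, dz, dy, da, db


@njit(cache=True)
def _integrate(state0, i_hold, i_step, on_idx, off_idx, n_samples, dt_ms, p):
    v, m, h, n, z, y, a, b = (state0[0], state0[1], state0[2], state0[3],
                              state0[4], state0[5], state0[6], state0[7])
    out = np.empty(n_samples)
    out[0] = v
    for i in range(1, n_samples):
        i_inj = i_step if on_idx <= i - 1 < off_idx else i_hold
        # classic RK4 step
        k1 = _derivs(v, m, h, n, z, y, a, b, i_inj, p)
        k2 = _derivs(v + 0.5 * dt_ms * k1[0], m + 0.5 * dt_ms * k1[1],
                     h + 0.5 * dt_ms * k1[2], n + 0.5 * dt_ms * k1[3],
                     z + 0.5 * dt_ms * k1[4], y + 0.5 * dt_ms * k1[5],
                     a + 0.5 * dt_ms * k1[6], b + 0.5 * dt_ms * k1[7], i_inj, p)
        k3 = _derivs(v + 0.5 * dt_ms * k2[0], m + 0.5 * dt_ms * k2[1],
                     h + 0.5 * dt_ms * k2[2], n + 0.5 * dt_ms * k2[3],
                     z + 0.5 * dt_ms * k2[4], y + 0.5 * dt_ms * k2[5],
                     a + 0.5 * dt_ms * k2[6], b + 0.5 * dt_ms * k2[7], i_inj, p)
        k4 = _derivs(v + dt_ms * k3[0], m + dt_ms * k3[1],
                     h + dt_ms * k3[2], n + dt_ms * k3[3],
                     z + dt_ms * k3[4], y + dt_ms * k3[5],
                     a + dt_ms * k3[6], b + dt_ms * k3[7], i_inj, p)
        v += dt_ms / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        m += dt_ms / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        h += dt_ms / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        n += dt_ms / 6.0 * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3])
        z += dt_ms / 6.0 * (k1[4] + 2 * k2[4] + 2 * k3[4] + k4[4])
        y += dt_ms / 6.0 * (k1[5] + 2 * k2[5] + 2 * k3[5] + k4[5])
        a += dt_ms / 6.0 * (k1[6] + 2 * k2[6] + 2 * k3[6] + k4[6])
        b += dt_ms / 6.0 * (k1[7] + 2 * k2[7] + 2 * k3[7] + k4[7])
        out[i] = v
    return out


def _pack_params(p: NeuronParams) -> np.ndarray:
    return np.array([
        p.c_m, p.g_leak, p.e_leak, p.g_na, p.e_na, p.g_kdr, p.e_k,
        p.g_adapt, p.tau_adapt,
        p.g_kir, p.kir_vhalf, p.kir_slope,
        p.g_hcn, p.hcn_vhalf, p.hcn_slope, p.e_hcn,
        p.g_atype, p.atype_act_vhalf, p.atype_act_slope,
        p.tau_hcn,
        p.atype_inact_vhalf, p.atype_inact_slope,
        p.atype_tau_act, p.atype_tau_inact,
        p.na_shift,
    ])


def standard_current_clamp_protocol(
    levels=None, holding: float = 0.0, onset: float = 0.1, duration: float = 1.0
) -> StepProtocol:
    """1 s depolarizing current steps in 10 pA increments from rest."""
    if levels is None:
        levels = np.arange(0.0, 101.0, 10.0)
    return StepProtocol(holding=holding, step_onset=onset,
                        step_offset=onset + duration, step_levels=np.asarray(levels, float))


def _upward_zero_crossings(v: np.ndarray, dt: float) -> np.ndarray:
    """Times (s) where the trajectory crosses 0 mV with positive slope."""
    below = v[:-1] < 0.0
    above = v[1:] >= 0.0
    idx = np.flatnonzero(below & above)
    frac = -v[idx] / (v[idx + 1] - v[idx])
    return (idx + frac) * dt


def simulate_current_clamp(
    params: NeuronParams,
    protocol: StepProtocol,
    dt: float = 2e-5,
    tail: float = 0.2,
    seed: int | None = None,
) -> tuple[SweepSeries, GroundTruth]:
    """Simulate a current-clamp step family with known spike times.

    ``protocol`` levels are pA relative to the holding current.  The model is
    initialised at the holding-current fixed point with all gates at steady
    state, so sweeps begin at rest with no onset transient.  The returned
    ground truth holds per-sweep spike times (0 mV upstroke crossings of the
    noiseless trajectory), the model's resting potential and the first
    spiking protocol level.
    """
    if dt > MAX_DT:
        raise ValueError(f"dt={dt} s too coarse for stable integration (max {MAX_DT})")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    v0 = params.resting_potential(protocol.holding)
    m0, h0, _ = (float(g) for g in hh_steady_gates(v0 - params.na_shift))
    n0 = float(hh_steady_gates(v0)[2])
    z0 = 1.0 / (1.0 + math.exp(-(v0 + 35.0) / 10.0))
    state0 = np.array([v0, m0, h0, n0, z0,
                       float(params.hcn_open(v0)),
                       float(params.atype_act(v0)),
                       float(params.atype_inact(v0))])
    n_samples = int(round((protocol.step_offset + tail) / dt))
    on_idx = int(round(protocol.step_onset / dt))
    off_idx = int(round(protocol.step_offset / dt))
    pvec = _pack_params(params)
    dt_ms = dt * 1e3

    sweeps, spike_times = [], []
    for level in protocol.step_levels:
        v = _integrate(state0, protocol.holding, protocol.holding + level,
                       on_idx, off_idx, n_samples, dt_ms, pvec)
        if not np.all(np.isfinite(v)):
            raise SimulationError(f"non-finite state; reduce dt (dt={dt} s)")
        spike_times.append(_upward_zero_crossings(v, dt))
        noisy = v + rng.normal(0.0, params.noise_sd_mV, size=v.size) \
            if params.noise_sd_mV > 0 else v
        sweeps.append(Trace(noisy, dt=dt, units="mV", role="membrane_voltage",
                            lowpass_cutoff=10e3))
    spiking = [lvl for lvl, st in zip(protocol.step_levels, spike_times) if st.size]
    series = SweepSeries(tuple(sweeps), protocol,
                         metadata={"clamp": "current", "junction_corrected": False})
    truth = GroundTruth(spike_times=spike_times,
                        resting_V=v0 if protocol.holding == 0 else params.resting_potential(0.0),
                        rheobase=float(spiking[0]) if spiking else None)
    return series, truth


def rheobase_dense_oracle(
    params: NeuronParams,
    protocol: StepProtocol,
    resolution: float = 1.0,
    dt: float = 2e-5,
) -> float | None:
    """Rheobase by brute force: re-simulate at ``resolution`` pA increments.

    Scans injection levels from the protocol minimum to maximum and returns
    the lowest level that fires, or None if none does.  Independent of any
    spike *detector* — spikes are the model's own 0 mV upstroke crossings.
    """
    lo = float(np.min(protocol.step_levels))
    hi = float(np.max(protocol.step_levels))
    quiet = replace_levels(protocol, np.array([lo]))
    for level in np.arange(lo, hi + resolution / 2, resolution):
        _, truth = simulate_current_clamp(
            params, replace_levels(protocol, np.array([level])), dt=dt)
        if truth.spike_times[0].size:
            return float(level)
    return None


def replace_levels(protocol: StepProtocol, levels: np.ndarray) -> StepProtocol:
    return StepProtocol(holding=protocol.holding, step_onset=protocol.step_onset,
                        step_offset=protocol.step_offset, step_levels=levels)
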