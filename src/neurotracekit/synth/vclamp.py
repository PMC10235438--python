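"""Voltage-clamp simulator with closed-form current families.

Because the command potential is piecewise constant, every gating variable
relaxes as a single exponential within each segment, so the clamp current
can be written down exactly — capacitive transient + leak + instantaneous
Kir + first-order HCN activation + A-type activation/inactivation — with no
numerical integration.  The "instantaneous vs steady-state" separation used
by the conductance estimators is therefore exact in the model, and the
ground truth can be evaluated on a dense voltage grid.
"""

from __future__ import annotations

import numpy as np

from ..trace_io import StepProtocol, SweepSeries, Trace
from .params import GroundTruth, NeuronParams

__all__ = [
    "simulate_voltage_clamp",
    "hyperpolarizing_protocol",
    "atype_protocol",
]


def hyperpolarizing_protocol(onset: float = 0.1, duration: float = 1.0) -> StepProtocol:
    """1 s hyperpolarizing steps, −60 to −130 mV in 10 mV increments."""
    return StepProtocol(holding=-60.0, step_onset=onset, step_offset=onset + duration,
                        step_levels=np.arange(-60.0, -131.0, -10.0))


def atype_protocol(onset: float = 0.1, duration: float = 0.5) -> StepProtocol:
    """500 ms depolarizing steps from −100 mV to −60…+35 mV in 5 mV increments."""
    return StepProtocol(holding=-100.0, step_onset=onset, step_offset=onset + duration,
                        step_levels=np.arange(-60.0, 35.1, 5.0))


def _atype_peak(params: NeuronParams, v: np.ndarray, t_ms: np.ndarray):
    """Peak A-type open probability and its time after a step from holding.

    Assumes full de-inactivation / deactivation at the holding potential
    (a0 = a_inf(holding), b0 = b_inf(holding)); returns (peak a·b, t_peak ms)
    per command potential by dense evaluation.
    """
    a_inf = params.atype_act(v)[:, None]
    b_inf = params.atype_inact(v)[:, None]
    a0 = params.atype_act(-100.0)
    b0 = params.atype_inact(-100.0)
    t = t_ms[None, :]
    a = a_inf + (a0 - a_inf) * np.exp(-t / params.atype_tau_act)
    b = b_inf + (b0 - b_inf) * np.exp(-t / params.atype_tau_inact)
    ab = a * b
    k = np.argmax(ab, axis=1)
    return ab[np.arange(v.size), k], t_ms[k]


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    return float(x @ (y - y.mean()) / (x @ x))


def measurable_conductances(params: NeuronParams, holding: float = -60.0) -> dict:
    """Ground-truth slope conductances as the protocol measures them.

    Evaluated on a dense noise-free voltage grid of the model's own current
    components: the Kir value is the difference of instantaneous slopes over
    −110…−130 vs −70…−90 mV; the HCN value is the slope of steady-minus-
    instantaneous current over −110…−130 mV; the A-type value is the slope
    of the peak subtracted current over −20…+35 mV.  All in nS.
    """
    y0 = params.hcn_open(holding)

    def inst_current(v):
        # leak + Kir + the (tiny) HCN conductance already open at holding
        return (params.g_leak * (v - params.e_leak)
                + params.g_kir * params.kir_open(v) * (v - params.e_k)
                + params.g_hcn * y0 * (v - params.e_hcn))

    v_lo = np.linspace(-130.0, -110.0, 201)
    v_hi = np.linspace(-90.0, -70.0, 201)
    kir = _ols_slope(v_lo, inst_current(v_lo)) - _ols_slope(v_hi, inst_current(v_hi))

    diff = params.g_hcn * (params.hcn_open(v_lo) - y0) * (v_lo - params.e_hcn)
    hcn = _ols_slope(v_lo, diff)

    v_a = np.linspace(-20.0, 35.0, 201)
    peak_ab, _ = _atype_peak(params, v_a, np.arange(0.0, 60.0, 0.01))
    atype = _ols_slope(v_a, params.g_atype * peak_ab * (v_a - params.e_k))
    return {
        "g_kir": params.g_kir, "g_hcn": params.g_hcn, "g_atype": params.g_atype,
        "g_leak": params.g_leak,
        "g_kir_measurable": kir, "g_hcn_measurable": hcn, "g_atype_measurable": atype,
    }


def simulate_voltage_clamp(
    params: NeuronParams,
    protocol: StepProtocol,
    blockers: frozenset | set = frozenset(),
    dt: float = 5e-5,
    tail: float = 0.1,
    seed: int | None = None,
) -> tuple[SweepSeries, GroundTruth]:
    """Simulate a voltage-clamp current family with known conductances.

    ``protocol`` levels are command potentials in mV; ``blockers`` may
    contain ``"atype_blocker"`` (emulating 4-AP), which zeroes the A-type
    term.  The current is capacitive transient + leak + instantaneous Kir +
    first-order HCN + A-type + white measurement noise.
    """
    bad = set(blockers) - {"atype_blocker"}
    if bad:
        raise ValueError(f"unknown blockers {bad}")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n = int(round((protocol.step_offset + tail) / dt))
    t = np.arange(n) * dt
    on, off = protocol.step_onset, protocol.step_offset
    hold = protocol.holding
    tau_c = params.tau_cap  # ms

    y0 = params.hcn_open(hold)
    a0 = params.atype_act(hold)
    b0 = params.atype_inact(hold)

    sweeps = []
    for v_step in protocol.step_levels:
        v_of_t = np.where((t >= on) & (t < off), v_step, hold)
        i = params.g_leak * (v_of_t - params.e_leak)
        i += params.g_kir * params.kir_open(v_of_t) * (v_of_t - params.e_k)

        # gating trajectories: exponential relaxation within each segment
        t_ms = t * 1e3
        on_ms, off_ms = on * 1e3, off * 1e3
        in_step = (t >= on) & (t < off)
        post = t >= off

        def relax(x0, x_inf_step, x_inf_hold, tau):
            x = np.full(n, x0)
            x[in_step] = x_inf_step + (x0 - x_inf_step) * np.exp(-(t_ms[in_step] - on_ms) / tau)
            x_off = x_inf_step + (x0 - x_inf_step) * np.exp(-(off_ms - on_ms) / tau)
            x[post] = x_inf_hold + (x_off - x_inf_hold) * np.exp(-(t_ms[post] - off_ms) / tau)
            return x

        y = relax(y0, params.hcn_open(v_step), y0, params.tau_hcn)
        i += params.g_hcn * y * (v_of_t - params.e_hcn)

        if "atype_blocker" not in blockers and params.g_atype > 0:
            a = relax(a0, params.atype_act(v_step), a0, params.atype_tau_act)
            b = relax(b0, params.atype_inact(v_step), b0, params.atype_tau_inact)
            i += params.g_atype * a * b * (v_of_t - params.e_k)

        # capacitive charging transients at both command edges
        dv = v_step - hold
        amp = params.c_m * dv / tau_c  # pA
        m_on, m_off = t >= on, t >= off
        i[m_on] += amp * np.exp(-(t_ms[m_on] - on_ms) / tau_c)
        i[m_off] += -amp * np.exp(-(t_ms[m_off] - off_ms) / tau_c)

        if params.noise_sd_pA > 0:
            i = i + rng.normal(0.0, params.noise_sd_pA, size=n)
        sweeps.append(Trace(i, dt=dt, units="pA", role="membrane_current",
                            lowpass_cutoff=2e3))

    series = SweepSeries(tuple(sweeps), protocol,
                         metadata={"clamp": "voltage",
                                   "blockers": sorted(blockers),
                                   "junction_corrected": False})
    truth = GroundTruth(conductances=measurable_conductances(params, holding=hold))
    return series, truth
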