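"""Model parameters and the ground-truth record shared by all generators."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np


class SimulationError(RuntimeError):
    """Raised when numerical integration produces non-finite state."""


@dataclass(frozen=True)
class NeuronParams:
    """Single-compartment conductance-based neuron.

    The spike-generating machinery is Hodgkin–Huxley-like (fast Na, delayed
    rectifier K); on top of it sit the subthreshold conductances that the
    voltage-clamp analyses measure — an instantaneous Boltzmann-rectified
    inward rectifier (Kir), a slowly activating h-current (HCN) and a rapidly
    activating/inactivating A-type K current — plus an optional slow
    adaptation (M-like) K conductance that produces spike-frequency
    accommodation.

    Units: capacitance pF, conductances nS, voltages mV, time constants ms.
    With these units ``dV/dt [mV/ms] = I [pA] / C [pF]`` holds directly.
    """

    c_m: float = 80.0           # pF
    g_leak: float = 4.0         # nS  (input resistance 250 MΩ)
    e_leak: float = -70.0       # mV
    # spike-generating conductances (squid-like kinetics, resting ≈ −70 mV)
    g_na: float = 9000.0
    e_na: float = 50.0
    na_shift: float = 0.0  # mV; shifts Na activation/inactivation voltage dependence
    g_kdr: float = 1200.0
    e_k: float = -77.0
    # slow adaptation (M-like) conductance → spike-frequency accommodation
    g_adapt: float = 4.0
    tau_adapt: float = 100.0    # ms
    # inward rectifier: instantaneous Boltzmann gate, open when hyperpolarized
    g_kir: float = 0.0
    kir_vhalf: float = -100.0
    kir_slope: float = 6.0
    # h-current: first-order activation, slow
    g_hcn: float = 0.0
    e_hcn: float = -30.0
    hcn_vhalf: float = -90.0
    hcn_slope: float = 8.0
    tau_hcn: float = 200.0      # ms
    # A-type K current: fast activation, slower inactivation
    g_atype: float = 0.0
    atype_act_vhalf: float = -25.0
    atype_act_slope: float = 12.0
    atype_tau_act: float = 2.0      # ms
    atype_inact_vhalf: float = -70.0
    atype_inact_slope: float = 6.0
    atype_tau_inact: float = 20.0   # ms
    # voltage-clamp capacitive transient time constant
    tau_cap: float = 1.0        # ms
    # measurement noise (white, Gaussian, added to the recorded channel)
    noise_sd_mV: float = 0.2
    noise_sd_pA: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("g_leak", "g_na", "g_kdr", "g_adapt", "g_kir", "g_hcn", "g_atype"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.c_m <= 0:
            raise ValueError("c_m must be positive")

    # steady-state gates (used by both the simulator and fixed-point search)

    def kir_open(self, v):
        return 1.0 / (1.0 + np.exp((v - self.kir_vhalf) / self.kir_slope))

    def hcn_open(self, v):
        return 1.0 / (1.0 + np.exp((v - self.hcn_vhalf) / self.hcn_slope))

    def atype_act(self, v):
        return 1.0 / (1.0 + np.exp(-(v - self.atype_act_vhalf) / self.atype_act_slope))

    def atype_inact(self, v):
        return 1.0 / (1.0 + np.exp((v - self.atype_inact_vhalf) / self.atype_inact_slope))

    def steady_current(self, v, i_inj: float = 0.0):
        """Net outward membrane current (pA) with all gates at steady state."""
        from .neuron import hh_steady_gates

        m, h, _ = hh_steady_gates(v - self.na_shift)
        _, _, n = hh_steady_gates(v)
        i = self.g_leak * (v - self.e_leak)
        i += self.g_na * m**3 * h * (v - self.e_na)
        i += self.g_kdr * n**4 * (v - self.e_k)
        z = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
        i += self.g_adapt * z * (v - self.e_k)
        i += self.g_kir * self.kir_open(v) * (v - self.e_k)
        i += self.g_hcn * self.hcn_open(v) * (v - self.e_hcn)
        i += self.g_atype * self.atype_act(v) * self.atype_inact(v) * (v - self.e_k)
        return i - i_inj

    def resting_potential(self, i_inj: float = 0.0) -> float:
        """Zero-current fixed point (mV) of the full steady-state I–V curve."""
        from scipy.optimize import brentq

        lo, hi = -110.0, -30.0
        if self.steady_current(lo, i_inj) * self.steady_current(hi, i_inj) > 0:
            raise ValueError("no resting fixed point in [-110, -30] mV")
        return float(brentq(lambda v: self.steady_current(v, i_inj), lo, hi, xtol=1e-9))


@dataclass
class GroundTruth:
    """Simulator-side record of the quantities analyses must recover.

    Only the fields relevant to the generator that produced it are set.
    Times are seconds, sorted; amplitudes are positive magnitudes.
    """

    # current clamp
    spike_times: list[np.ndarray] | None = None   # one array per sweep
    resting_V: float | None = None                # mV, model fixed point
    rheobase: float | None = None                 # pA, first spiking protocol level
    # voltage clamp
    conductances: dict[str, float] | None = None  # raw and measurable values, nS
    # mEPSC
    mepsc_times: np.ndarray | None = None         # s
    mepsc_amplitudes: np.ndarray | None = None    # pA, positive
    warning: str | None = None
    # calcium field
    calcium_event_times: np.ndarray | None = None
    calcium_event_amplitudes: np.ndarray | None = None  # population-mean dF/F peaks
    calcium_supra_criterion: np.ndarray | None = None   # bool per event (1/10 rule)
    bic_reference_peak: float | None = None
    # cell image
    nuclear_intensity: float | None = None
    cytoplasmic_intensity: float | None = None
    nuc_cyto_ratio: float | None = None
    # qPCR
    proportions: dict[str, float] | None = None   # gene -> true nuclear proportion
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("mepsc_times", "calcium_event_times"):
            t = getattr(self, name)
            if t is not None and np.any(np.diff(t) < 0):
                raise ValueError(f"{name} must be sorted")

    def to_json(self, path: str | Path | None = None) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            raise TypeError(type(o))

        text = json.dumps(asdict(self), default=default, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text
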