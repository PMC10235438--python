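"""Slope-conductance estimation from voltage-clamp current families.

Three hyperpolarization/depolarization-activated K-family conductances are
measured exactly as the recordings define them:

* **Kir** — difference between the instantaneous slope conductance over
  −110…−130 mV and over −70…−90 mV (inward rectification makes the
  hyperpolarized slope larger; reported positive for inward rectifiers).
* **HCN** — slope of the steady-state-minus-instantaneous current over
  −110…−130 mV (the h-current activates slowly, so it appears only in the
  steady-state measurement).
* **A-type** — after digital subtraction of a 4-AP-blocked family from its
  control, the slope of the rapidly inactivating peak current (3–13 ms
  after the step) against command potential over −20…+35 mV.

Instantaneous currents are read directly after the capacitive transient,
whose end is detected with a |dI/dt| criterion; steady-state currents at
the end of the step.  All slopes are unconstrained least squares; pA/mV
is nS directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trace_io import SweepSeries

__all__ = [
    "IVTable",
    "ConductanceSet",
    "measure_step_currents",
    "slope_conductance",
    "kir_conductance",
    "hcn_conductance",
    "atype_conductance",
]


@dataclass(frozen=True)
class IVTable:
    """Per-sweep instantaneous and steady-state currents (mV, pA)."""

    command_V: np.ndarray
    instantaneous: np.ndarray
    steady: np.ndarray
    flags: dict[float, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.command_V, float)
        d = np.diff(v)
        if v.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("command potentials must be strictly monotone")
        for name in ("instantaneous", "steady"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite {name} current")

    @property
    def difference(self) -> np.ndarray:
        """Steady-state minus instantaneous current (the slow component)."""
        return self.steady - self.instantaneous

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"command_mV": self.command_V,
                             "instantaneous_pA": self.instantaneous,
                             "steady_pA": self.steady})


@dataclass(frozen=True)
class ConductanceSet:
    g_kir: float | None = None    # nS
    g_hcn: float | None = None
    g_atype: float | None = None
    diagnostics: dict = field(default_factory=dict)  # residual sd per fit


def _transient_end(i: np.ndarray, i_on: int, dt: float, noise_sd: float,
                   max_ms: float = 40.0) -> int:
    """Sample where the capacitive transient has decayed into the noise.

    The transient is characterised per sweep: its amplitude is the jump of
    the current at the step relative to a provisional post-transient level,
    and its time constant comes from a log-linear fit of the early decay.
    The returned index is where the fitted exponential reaches twice the
    baseline noise sd (a fixed small fraction of the amplitude when the
    sweep is noise-free), so the residual inside the instantaneous window
    is uniform across sweeps instead of tracking the step size.
    """
    ref0 = i_on + int(round(10e-3 / dt))
    ref1 = i_on + int(round(15e-3 / dt))
    rough = float(np.mean(i[ref0:max(ref1, ref0 + 1)]))
    resid = i[i_on:i_on + int(round(max_ms * 1e-3 / dt))] - rough
    amp = resid[0]
    floor = max(2.0 * noise_sd, 1e-4 * abs(amp), 1e-12)
    if abs(amp) <= max(5.0 * noise_sd, 1e-12):
        return i_on  # no appreciable transient
    # tau from the early, high-SNR part of the decay
    big = np.abs(resid) > max(10.0 * noise_sd, 0.05 * abs(amp))
    n_fit = int(np.argmin(big)) if not big.all() else big.size
    n_fit = min(n_fit, int(round(5e-3 / dt)))
    if n_fit < 3:
        return i_on + n_fit
    t = np.arange(n_fit) * dt
    tau = -1.0 / np.polyfit(t, np.log(np.abs(resid[:n_fit])), 1)[0]
    tau = min(max(tau, 0.05e-3), 5e-3)
    t_end = tau * np.log(abs(amp) / floor)
    return i_on + int(np.ceil(t_end / dt))


def measure_step_currents(
    series: SweepSeries,
    inst_window: tuple[float, float] = (0.0, 5.0),
    ss_window: tuple[float, float] = (100.0, 100.0),
) -> IVTable:
    """Instantaneous and steady-state current per sweep of a voltage-clamp family.

    ``inst_window = (delay, width)`` in ms places the instantaneous-current
    mean ``delay`` ms after the detected end of the capacitive transient;
    ``ss_window = (lead, width)`` places the steady-state mean ``lead`` ms
    before the step end.  Sweeps whose transient never settles before the
    instantaneous window are measured at the latest possible window and
    flagged.
    """
    prot = series.protocol
    dt = series.dt
    i_on = series.sweeps[0].index_at(prot.step_onset)
    i_off = series.sweeps[0].index_at(prot.step_offset)
    inst, steady = [], []
    flags: dict[float, str] = {}
    for level, sweep in zip(prot.step_levels, series.sweeps):
        x = sweep.samples
        noise_sd = float(np.diff(x[:i_on]).std() / np.sqrt(2.0)) if i_on > 2 else 0.0
        i_end = _transient_end(x, i_on, dt, noise_sd)
        a = i_end + int(round(inst_window[0] * 1e-3 / dt))
        b = a + max(1, int(round(inst_window[1] * 1e-3 / dt)))
        if b > i_off:
            flags[float(level)] = "transient overlaps instantaneous window; shifted"
            b = i_off
            a = max(i_on, b - max(1, int(round(inst_window[1] * 1e-3 / dt))))
        inst.append(x[a:b].mean())
        s0 = i_off - int(round(ss_window[0] * 1e-3 / dt))
        s1 = s0 + max(1, int(round(ss_window[1] * 1e-3 / dt)))
        steady.append(x[s0:min(s1, i_off)].mean())
    return IVTable(command_V=np.asarray(prot.step_levels, float),
                   instantaneous=np.asarray(inst), steady=np.asarray(steady),
                   flags=flags)


def slope_conductance(
    iv: IVTable,
    column: str = "instantaneous",
    v_range: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Least-squares slope (nS) of a current column against command potential.

    ``column`` is ``instantaneous``, ``steady`` or ``difference``; rows are
    restricted to ``v_range`` (inclusive) when given.  Returns
    ``(slope_nS, residual_sd_pA)``.
    """
    i = {"instantaneous": iv.instantaneous, "steady": iv.steady,
         "difference": iv.difference}[column]
    v = iv.command_V
    if v_range is not None:
        lo, hi = min(v_range), max(v_range)
        m = (v >= lo) & (v <= hi)
        v, i = v[m], i[m]
    if v.size < 2:
        raise ValueError(f"fewer than 2 rows in voltage range {v_range}")
    slope, intercept = np.polyfit(v, i, 1)
    resid = i - (slope * v + intercept)
    return float(slope), float(resid.std())


def kir_conductance(iv: IVTable) -> tuple[float, dict]:
    """Inward-rectifier conductance (nS) from the instantaneous I–V curve.

    Difference of instantaneous slope conductances, −110…−130 mV minus
    −70…−90 mV.  Sign convention: positive for an inward rectifier (the
    conductance grows with hyperpolarization); leak cancels in the
    subtraction.
    """
    g_hyper, r1 = slope_conductance(iv, "instantaneous", (-130.0, -110.0))
    g_depol, r2 = slope_conductance(iv, "instantaneous", (-90.0, -70.0))
    return g_hyper - g_depol, {"residual_sd": (r1, r2)}


def hcn_conductance(iv: IVTable) -> tuple[float, dict]:
    """HCN (h-current) conductance (nS): slope of steady − instantaneous
    current over −110…−130 mV, where activation is saturated."""
    g, r = slope_conductance(iv, "difference", (-130.0, -110.0))
    return g, {"residual_sd": r}


def atype_conductance(
    control: SweepSeries,
    blocked: SweepSeries,
    v_range: tuple[float, float] = (-20.0, 35.0),
    peak_window: tuple[float, float] = (3.0, 13.0),
    search_ms: float = 30.0,
) -> tuple[float, dict]:
    """A-type conductance (nS) by digital subtraction of a 4-AP-blocked family.

    Per command level the blocked sweep is subtracted from its control
    (paired by level, not sweep order); the transient outward peak is
    located within ``search_ms`` after the step and must fall inside
    ``peak_window`` ms (sweeps peaking outside are flagged and excluded).
    The conductance is the least-squares slope of peak current against
    command potential over ``v_range``.
    """
    pc, pb = control.protocol, blocked.protocol
    if not (np.array_equal(pc.step_levels, pb.step_levels)
            and pc.step_onset == pb.step_onset and pc.step_offset == pb.step_offset):
        raise ValueError("control and blocked families have mismatched protocols")
    dt = control.dt
    if blocked.dt != dt or control.sweeps[0].n != blocked.sweeps[0].n:
        raise ValueError("control and blocked sweeps are not sample-aligned")
    i_on = control.sweeps[0].index_at(pc.step_onset)
    i_hi = i_on + int(round(search_ms * 1e-3 / dt))
    vs, peaks = [], []
    flagged: dict[float, float] = {}
    for level in pc.step_levels:
        d = (control.sweep_for_level(level).samples
             - blocked.sweep_for_level(level).samples)
        seg = d[i_on:i_hi]
        noise_sd = float(d[:i_on].std()) if i_on > 2 else 0.0
        k = int(np.argmax(seg))
        if seg[k] <= max(5.0 * noise_sd, 1e-9):
            # no resolvable subtracted current at this level: peak is zero
            vs.append(level)
            peaks.append(0.0)
            continue
        t_pk = k * dt * 1e3  # ms post-onset
        if not peak_window[0] <= t_pk <= peak_window[1]:
            flagged[float(level)] = t_pk
            continue
        vs.append(level)
        peaks.append(seg[k])
    vs, peaks = np.asarray(vs, float), np.asarray(peaks)
    lo, hi = v_range
    m = (vs >= lo) & (vs <= hi)
    if m.sum() < 2:
        raise ValueError("fewer than 2 usable peak currents in the fit range")
    slope, intercept = np.polyfit(vs[m], peaks[m], 1)
    resid = peaks[m] - (slope * vs[m] + intercept)
    return float(slope), {"residual_sd": float(resid.std()),
                          "peak_time_flags": flagged, "n_fit": int(m.sum())}
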