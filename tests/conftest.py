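import numpy as np
import pytest

from neurotracekit.synth import (
    NeuronParams,
    hyperpolarizing_protocol,
    simulate_current_clamp,
    simulate_voltage_clamp,
    standard_current_clamp_protocol,
)


def random_neuron(rng: np.random.Generator, noise_sd_mV: float = 0.2,
                  **overrides) -> NeuronParams:
    """A physiologically plausible random neuron for property tests."""
    kw = dict(
        c_m=rng.uniform(60.0, 100.0),
        g_leak=rng.uniform(3.0, 5.0),
        g_na=rng.uniform(7500.0, 11000.0),
        g_kdr=rng.uniform(1000.0, 1500.0),
        g_adapt=rng.uniform(0.0, 8.0),
        noise_sd_mV=noise_sd_mV,
        seed=int(rng.integers(2**31 - 1)),
    )
    kw.update(overrides)
    return NeuronParams(**kw)


@pytest.fixture(scope="session")
def cc_protocol():
    return standard_current_clamp_protocol()


@pytest.fixture(scope="session")
def default_family(cc_protocol):
    """Current-clamp family of the default neuron, shared across tests."""
    params = NeuronParams(seed=7)
    series, truth = simulate_current_clamp(params, cc_protocol)
    return params, series, truth


@pytest.fixture(scope="session")
def passive_family():
    """Noise-free passive (non-spiking) hyperpolarizing family."""
    params = NeuronParams(g_na=0.0, g_kdr=0.0, g_adapt=0.0, noise_sd_mV=0.0)
    protocol = standard_current_clamp_protocol(levels=np.arange(-50.0, 0.0, 10.0))
    series, truth = simulate_current_clamp(params, protocol)
    return params, series, truth


@pytest.fixture(scope="session")
def kir_hcn_family():
    params = NeuronParams(g_kir=3.0, g_hcn=5.0, seed=11)
    series, truth = simulate_voltage_clamp(params, hyperpolarizing_protocol())
    return params, series, truth
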