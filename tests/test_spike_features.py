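import numpy as np
import pytest

from neurotracekit.spike_features import (
    accommodation_index,
    ap_features,
    detect_aps,
    io_curve_from_held,
    rheobase_analysis,
)
from neurotracekit.synth import (
    NeuronParams,
    simulate_current_clamp,
    standard_current_clamp_protocol,
)
from neurotracekit.trace_io import Trace

from _oracles import brute_force_ap_features, brute_force_detect
from conftest import random_neuron


def truth_count(spike_times, protocol, margin=0.005):
    """Ground-truth AP count inside the injection window.

    A spike whose 0 mV crossing falls within ``margin`` s after the step
    offset was initiated during the step and is counted.
    """
    return int(np.sum((spike_times >= protocol.step_onset)
                      & (spike_times <= protocol.step_offset + margin)))


def synthetic_spike(dt=4e-6, base=-50.0, peak=40.0, rise_ms=0.9, fall_ms=1.8):
    """Piecewise-linear AP waveform with analytically known features."""
    pre = np.full(int(5e-3 / dt), base)
    rise = np.linspace(base, peak, int(rise_ms * 1e-3 / dt), endpoint=False)
    fall = np.linspace(peak, base - 10.0, int(fall_ms * 1e-3 / dt), endpoint=False)
    post_trough = np.linspace(base - 10.0, base, int(2e-3 / dt), endpoint=False)
    post = np.full(int(5e-3 / dt), base)
    v = np.concatenate([pre, rise, fall, post_trough, post])
    return Trace(v, dt=dt, units="mV", role="membrane_voltage")


class TestDetectAps:
    def test_passive_sweep_has_no_detections(self, passive_family):
        _, series, _ = passive_family
        for sweep in series.sweeps:
            assert detect_aps(sweep) == []

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed, cc_protocol):
        """Detector equals an independent derivative-scan reimplementation."""
        rng = np.random.default_rng(seed)
        params = random_neuron(rng)
        prot = standard_current_clamp_protocol(levels=np.array([80.0]))
        series, _ = simulate_current_clamp(params, prot)
        sweep = series.sweeps[0]
        window = (prot.step_onset, prot.step_offset)
        got = detect_aps(sweep, window=window, onset=prot.step_onset)
        want = brute_force_detect(sweep.samples, sweep.dt, window,
                                  onset=prot.step_onset)
        assert got == want

    def test_spike_near_onset_is_blanked(self):
        trace = synthetic_spike()
        onset = 4e-3  # spike upstroke starts 1 ms after this onset
        with_blank = detect_aps(trace, onset=onset, onset_blank=5.0)
        without = detect_aps(trace)
        assert len(without) == 1
        assert with_blank == []

    def test_window_outside_trace_raises(self):
        trace = synthetic_spike()
        with pytest.raises(IndexError):
            detect_aps(trace, window=(0.0, 10.0 * trace.duration))

    def test_offset_invariance(self):
        """A constant voltage offset moves voltages, not detections."""
        params = NeuronParams(seed=3, noise_sd_mV=0.1)
        prot = standard_current_clamp_protocol(levels=np.array([80.0]))
        series, _ = simulate_current_clamp(params, prot)
        sweep = series.sweeps[0]
        det = detect_aps(sweep, window=(prot.step_onset, prot.step_offset))
        for offset in (-10.0, 7.5):
            shifted = Trace(sweep.samples + offset, sweep.dt, "mV",
                            "membrane_voltage")
            det2 = detect_aps(shifted, window=(prot.step_onset, prot.step_offset))
            assert det2 == det
            f1 = ap_features(sweep, det[0])
            f2 = ap_features(shifted, det2[0])
            assert f2.threshold_V - f1.threshold_V == pytest.approx(offset, abs=1e-9)
            assert f2.threshold_time == f1.threshold_time
            assert f2.half_width == pytest.approx(f1.half_width, abs=1e-9)


class TestApFeatures:
    def test_piecewise_linear_spike_has_analytic_features(self):
        trace = synthetic_spike()
        det = detect_aps(trace)
        assert len(det) == 1
        f = ap_features(trace, det[0])
        # rise is linear at 100 mV/ms, so the 20 mV/ms crossing sits at the
        # first rise sample and the threshold voltage is the baseline
        assert f.threshold_V == pytest.approx(-50.0, abs=0.5)
        assert f.amplitude == pytest.approx(90.0, abs=0.5)
        # half-amplitude level −5 mV: rise at 100 mV/ms covers 45 mV in
        # 0.45 ms; fall at 55.6 mV/ms covers 45 mV in 0.81 ms
        assert f.half_width == pytest.approx(0.45 + 0.81, abs=0.02)
        assert f.ahp_V == pytest.approx(-60.0, abs=0.5)
        assert f.ahp_amplitude == pytest.approx(10.0, abs=0.6)

    def test_features_match_brute_force_on_simulated_spike(self, default_family):
        _, series, _ = default_family
        exc = rheobase_analysis(series)
        sweep = series.sweep_for_level(exc.rheobase)
        det = detect_aps(sweep, window=(series.protocol.step_onset,
                                        series.protocol.step_offset),
                         onset=series.protocol.step_onset)
        i, p = det[0]
        f = ap_features(sweep, det[0])
        thr_v, amp, hw = brute_force_ap_features(sweep.samples, sweep.dt, i, p)
        assert f.threshold_V == pytest.approx(thr_v, abs=1e-9)
        assert f.amplitude == pytest.approx(amp, abs=1e-9)
        assert f.half_width == pytest.approx(hw, abs=1e-9)

    def test_missing_trough_is_flagged(self):
        dt = 4e-6
        rise = np.linspace(-50, 40, 300)
        fall = np.linspace(40, 30, 100)  # never repolarises
        v = np.concatenate([np.full(500, -50.0), rise, fall])
        trace = Trace(v, dt=dt, units="mV", role="membrane_voltage")
        det = detect_aps(trace)
        f = ap_features(trace, det[0])
        assert f.ahp_V is None and f.ahp_flag is not None


class TestAccommodation:
    def test_regular_train_gives_exactly_one(self):
        assert accommodation_index(np.arange(0.0, 1.0, 0.1)) == pytest.approx(
            1.0, abs=1e-12)

    def test_constructed_train_arithmetic(self):
        t = np.array([0.0, 0.01, 0.03, 0.07, 0.15, 0.31])
        assert accommodation_index(t) == pytest.approx(16.0)
        assert accommodation_index(t, direction="first_over_last") == \
            pytest.approx(1 / 16.0)

    def test_fewer_than_six_aps_gives_none(self):
        assert accommodation_index(np.arange(5) * 0.1) is None

    def test_monotone_in_adaptation_conductance(self):
        """More adaptation conductance, more spike-frequency accommodation."""
        prot = standard_current_clamp_protocol(levels=np.array([80.0]))
        indices = []
        for g_adapt in (0.0, 2.0, 5.0, 10.0, 20.0):
            p = NeuronParams(g_adapt=g_adapt, noise_sd_mV=0.0)
            _, truth = simulate_current_clamp(p, prot)
            indices.append(accommodation_index(truth.spike_times[0]))
        assert all(b > a for a, b in zip(indices, indices[1:]))


class TestRheobase:
    def test_family_rheobase_matches_ground_truth(self, default_family):
        _, series, truth = default_family
        exc = rheobase_analysis(series)
        assert exc.rheobase == truth.rheobase
        assert exc.first_ap is not None and exc.first_ap.amplitude > 50

    def test_subthreshold_family_has_absent_rheobase(self, passive_family):
        _, series, _ = passive_family
        exc = rheobase_analysis(series)
        assert exc.rheobase is None and "no_spiking_sweep" in exc.flags
        assert all(c == 0 for c in exc.io_curve.values())

    def test_five_pa_increments_accepted(self):
        p = NeuronParams(seed=2)
        prot = standard_current_clamp_protocol(levels=np.arange(40.0, 61.0, 5.0))
        series, truth = simulate_current_clamp(p, prot)
        exc = rheobase_analysis(series)
        assert exc.rheobase == truth.rheobase

    def test_io_curve_monotone_for_deterministic_model(self, default_family):
        _, series, _ = default_family
        exc = rheobase_analysis(series)
        counts = [exc.io_curve[float(l)] for l in series.protocol.step_levels]
        assert counts == sorted(counts)

    def test_io_counts_match_simulator_truth(self, default_family):
        _, series, truth = default_family
        exc = rheobase_analysis(series)
        prot = series.protocol
        for level, st in zip(prot.step_levels, truth.spike_times):
            boundary = np.any(np.abs(st - prot.step_offset) < 0.006)
            if boundary:
                continue  # spike straddling the window edge: convention-dependent
            assert exc.io_curve[float(level)] == truth_count(st, prot)


class TestHeldIOCurve:
    def test_counts_from_held_potential(self):
        p = NeuronParams(seed=13)
        hold = (-70.0 - p.resting_potential()) * p.g_leak  # rough bias current
        prot = standard_current_clamp_protocol(
            levels=np.arange(0.0, 101.0, 20.0), holding=hold)
        series, truth = simulate_current_clamp(p, prot)
        base = series.sweeps[0].samples[:series.sweeps[0].index_at(0.09)].mean()
        curve, flags = io_curve_from_held(series, held_V=base, tolerance=3.0)
        assert not flags
        for level, st in zip(prot.step_levels, truth.spike_times):
            if np.any(np.abs(st - prot.step_offset) < 0.006):
                continue
            assert curve[float(level)] == truth_count(st, prot)

    def test_zero_amplitude_step_counts_zero(self, default_family):
        _, series, _ = default_family
        curve, _ = io_curve_from_held(
            series, held_V=series.sweeps[0].samples[:100].mean())
        assert curve[0.0] == 0

    def test_drifted_baseline_is_flagged_and_excluded(self, default_family):
        _, series, _ = default_family
        curve, flags = io_curve_from_held(series, held_V=-60.0, tolerance=3.0)
        assert curve == {} and len(flags) == series.n_sweeps
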