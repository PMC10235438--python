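"""Generator-level checks: determinism, closed-form limits, ground truth."""

import numpy as np
import pytest

from neurotracekit.synth import (
    NeuronParams,
    SimulationError,
    atype_protocol,
    hyperpolarizing_protocol,
    simulate_calcium_field,
    simulate_cell_image,
    simulate_ct_table,
    simulate_current_clamp,
    simulate_mepsc,
    simulate_voltage_clamp,
    standard_current_clamp_protocol,
)
from neurotracekit.synth.events import biexp_kernel_peak


class TestDeterminism:
    def test_identical_seed_bit_identical_outputs(self, cc_protocol):
        p = NeuronParams(seed=3)
        s1, _ = simulate_current_clamp(p, cc_protocol)
        s2, _ = simulate_current_clamp(p, cc_protocol)
        for a, b in zip(s1.sweeps, s2.sweeps):
            np.testing.assert_array_equal(a.samples, b.samples)
        t1, _ = simulate_mepsc(seed=5)
        t2, _ = simulate_mepsc(seed=5)
        np.testing.assert_array_equal(t1.samples, t2.samples)
        r1, g1 = simulate_calcium_field(seed=9)
        r2, g2 = simulate_calcium_field(seed=9)
        np.testing.assert_array_equal(r1.traces[0].samples, r2.traces[0].samples)
        np.testing.assert_array_equal(g1.calcium_event_times, g2.calcium_event_times)
        i1, _ = simulate_cell_image(noise_sd=5.0, seed=2)
        i2, _ = simulate_cell_image(noise_sd=5.0, seed=2)
        np.testing.assert_array_equal(i1, i2)


class TestCurrentClamp:
    def test_passive_charge_balance(self):
        """With spiking conductances off, steady ΔV = ΔI / g_leak exactly."""
        p = NeuronParams(g_na=0.0, g_kdr=0.0, g_adapt=0.0, noise_sd_mV=0.0,
                         g_leak=5.0)
        prot = standard_current_clamp_protocol(levels=np.array([-20.0, -10.0]))
        series, truth = simulate_current_clamp(p, prot)
        for level, sweep in zip(prot.step_levels, series.sweeps):
            v_end = sweep.samples[sweep.index_at(prot.step_offset) - 1]
            assert v_end - truth.resting_V == pytest.approx(level / 5.0, abs=1e-6)
            assert not (
                len(truth.spike_times[0]) or len(truth.spike_times[1])
            )

    def test_resting_potential_matches_fixed_point(self, cc_protocol):
        p = NeuronParams(noise_sd_mV=0.0, seed=1)
        series, truth = simulate_current_clamp(p, cc_protocol)
        baseline = series.sweeps[0].samples[: series.sweeps[0].index_at(0.09)]
        assert abs(baseline[-1] - truth.resting_V) < 0.5

    def test_coarse_dt_rejected(self, cc_protocol):
        with pytest.raises(ValueError, match="dt"):
            simulate_current_clamp(NeuronParams(), cc_protocol, dt=1e-4)

    def test_ten_pa_increment_family_reports_rheobase(self, default_family):
        _, series, truth = default_family
        assert truth.rheobase is not None
        assert truth.rheobase in series.protocol.step_levels
        idx = list(series.protocol.step_levels).index(truth.rheobase)
        assert all(t.size == 0 for t in truth.spike_times[:idx])


class TestVoltageClamp:
    def test_pure_leak_iv_is_linear_with_leak_slope(self):
        p = NeuronParams(g_kir=0.0, g_hcn=0.0, noise_sd_pA=0.0, g_leak=4.0)
        series, _ = simulate_voltage_clamp(p, hyperpolarizing_protocol())
        dt = series.dt
        i_ss = [sw.samples[int(1.05 / dt)] for sw in series.sweeps]
        slope = np.polyfit(series.protocol.step_levels, i_ss, 1)[0]
        assert slope == pytest.approx(4.0, rel=1e-9)

    def test_no_hcn_means_steady_equals_instantaneous(self):
        p = NeuronParams(g_kir=2.0, g_hcn=0.0, noise_sd_pA=0.0)
        series, _ = simulate_voltage_clamp(p, hyperpolarizing_protocol())
        dt = series.dt
        for sweep in series.sweeps[-3:]:  # −110..−130 mV
            inst = sweep.samples[int(0.115 / dt):int(0.120 / dt)].mean()
            steady = sweep.samples[int(1.0 / dt):int(1.09 / dt)].mean()
            # equal up to the last trace of the capacitive transient
            assert steady == pytest.approx(inst, abs=1e-2)

    def test_blocker_zeroes_the_atype_component(self):
        p = NeuronParams(g_atype=20.0, noise_sd_pA=0.0)
        ctrl, _ = simulate_voltage_clamp(p, atype_protocol())
        blk, _ = simulate_voltage_clamp(p, atype_protocol(),
                                        blockers={"atype_blocker"})
        zero, _ = simulate_voltage_clamp(
            NeuronParams(g_atype=0.0, noise_sd_pA=0.0), atype_protocol())
        np.testing.assert_allclose(blk.sweeps[-1].samples,
                                   zero.sweeps[-1].samples, atol=1e-9)
        assert np.max(ctrl.sweeps[-1].samples - blk.sweeps[-1].samples) > 100.0

    def test_unknown_blocker_rejected(self):
        with pytest.raises(ValueError, match="unknown blockers"):
            simulate_voltage_clamp(NeuronParams(), hyperpolarizing_protocol(),
                                   blockers={"ttx"})

    def test_protocols_match_recording_conventions(self):
        hp = hyperpolarizing_protocol()
        np.testing.assert_array_equal(hp.step_levels, np.arange(-60., -131., -10.))
        assert hp.step_duration == pytest.approx(1.0)
        ap = atype_protocol()
        assert ap.holding == -100.0 and ap.step_duration == pytest.approx(0.5)
        assert ap.step_levels[0] == -60.0 and ap.step_levels[-1] == 35.0


class TestMepsc:
    def test_poisson_count_concentration(self):
        _, truth = simulate_mepsc(rate=0.5, duration=600.0, seed=4)
        assert abs(truth.mepsc_times.size - 300) <= 3 * np.sqrt(300)

    def test_single_event_peak_matches_closed_form(self):
        _, kp = biexp_kernel_peak(0.5, 5.0)
        assert 0 < kp < 1
        trace, truth = simulate_mepsc(noise_sd=0.0, duration=2.0, rate=1e-6,
                                      event_times=np.array([1.0]),
                                      amp_dist=(20.0, 0.0), seed=0)
        assert -trace.samples.min() == pytest.approx(truth.mepsc_amplitudes[0],
                                                     rel=1e-3)

    def test_default_duration_yields_at_least_200_events(self):
        _, truth = simulate_mepsc(seed=1)
        assert truth.mepsc_times.size >= 200
        assert truth.warning is None

    def test_too_short_duration_warns(self):
        _, truth = simulate_mepsc(rate=0.1, duration=2.0, seed=0)
        assert truth.warning is not None


class TestCalciumField:
    def test_events_and_reference_by_construction(self):
        rois, truth = simulate_calcium_field(seed=0)
        assert truth.calcium_event_times.size == 4
        assert rois.bic_marker == 1200  # 600 s at 2 Hz
        assert truth.bic_reference_peak == pytest.approx(1.0, abs=0.05)
        assert truth.calcium_supra_criterion.all()

    def test_subcriterion_events_labelled(self):
        _, truth = simulate_calcium_field(event_amp=0.05, seed=0)
        assert not truth.calcium_supra_criterion.any()

    def test_event_separation_enforced(self):
        with pytest.raises(ValueError, match="separated"):
            simulate_calcium_field(event_times=np.array([100.0, 103.0]), seed=0)

    def test_roi_count_range_enforced(self):
        with pytest.raises(ValueError, match="15-30"):
            simulate_calcium_field(n_rois=5, seed=0)


class TestCellImage:
    @pytest.mark.parametrize("nuc,cyto,expected", [(200., 100., 2.0),
                                                   (100., 100., 1.0)])
    def test_ground_truth_ratio(self, nuc, cyto, expected):
        _, truth = simulate_cell_image(nuc_intensity=nuc, cyto_intensity=cyto)
        assert truth.nuc_cyto_ratio == expected

    def test_bad_geometry_rejected(self):
        with pytest.raises(ValueError):
            simulate_cell_image(geometry=(25, 10))
        with pytest.raises(ValueError):
            simulate_cell_image(geometry=(0, 10))


class TestCtTable:
    def test_table_round_trips_proportions(self):
        table, truth = simulate_ct_table(ct_noise_sd=0.0, seed=0)
        wide = table.pivot_table(index=["gene", "replicate"],
                                 columns="fraction", values="ct")
        delta = (wide["nuclear"] - wide["cytoplasmic"]).groupby("gene").mean()
        for gene, p in truth.proportions.items():
            assert delta[gene] == pytest.approx(np.log2((1 - p) / p), abs=1e-9)
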