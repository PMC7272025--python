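"""F-I machinery: curve building, sigmoid fits, rheobase, classification."""

import numpy as np
import pytest

from fsinephys import (
    FICurve,
    build_fi_curve,
    classify_cell,
    detect_spikes,
    fit_fi_sigmoid,
    fs_preset,
    rheobase,
    select_rheobase_plus,
    simulate_current_clamp,
    threshold_from_ramp,
    theoretical_rheobase,
)
from fsinephys.synthetic_data import ProtocolSpec, apply_effects, default_protocols

from conftest import make_triangle_spike_sweep


def sigmoid(i, fmax, xhalf, k):
    return fmax / (1.0 + np.exp(-(np.asarray(i) - xhalf) / k))


class TestBuildFICurve:
    def test_rate_is_spikes_per_second(self):
        # 4 spikes in a 100 ms window -> 40 Hz
        sw = make_triangle_spike_sweep([30, 50, 70, 90], duration_ms=140.0,
                                       onset_ms=20.0)
        curve = build_fi_curve([sw])
        assert curve.rates[0] == pytest.approx(4 / 0.1)

    def test_spikes_outside_step_window_not_counted(self):
        sw = make_triangle_spike_sweep([10.0, 50.0], duration_ms=140.0, onset_ms=20.0)
        curve = build_fi_curve([sw])  # spike at 10 ms precedes the step
        assert curve.rates[0] == pytest.approx(1 / 0.1)

    def test_generator_curve_matches_detector_counts(self, fs_fi_sweeps):
        curve = build_fi_curve(fs_fi_sweeps)
        for sw, rate in zip(fs_fi_sweeps, curve.rates):
            i0, i1 = sw.stimulus_window()
            n = len([p for p in detect_spikes(sw) if i0 <= p < i1])
            assert rate == pytest.approx(n / 0.8)

    def test_mixed_durations_rejected(self):
        a = make_triangle_spike_sweep([50.0], duration_ms=140.0)
        b = make_triangle_spike_sweep([50.0], duration_ms=200.0)
        b.stimulus = a.stimulus.__class__(200.0, 10.0, 150.0, "step")
        with pytest.raises(ValueError, match="durations"):
            build_fi_curve([a, b])


class TestSigmoidFit:
    def test_exact_points_recovered_within_1pct(self):
        i = np.arange(25.0, 301.0, 25.0)
        curve = FICurve(i, sigmoid(i, 250.0, 150.0, 25.0), 800.0)
        fit = fit_fi_sigmoid(curve)
        assert fit.max_rate == pytest.approx(250.0, rel=0.01)
        assert fit.xhalf == pytest.approx(150.0, rel=0.01)
        assert fit.k == pytest.approx(25.0, rel=0.01)
        assert fit.rising_rate == pytest.approx(250.0 / 100.0, rel=0.01)

    def test_noisy_xhalf_within_half_step_over_100_seeds(self):
        i = np.arange(25.0, 301.0, 25.0)
        clean = sigmoid(i, 250.0, 150.0, 25.0)
        for seed in range(100):
            rng = np.random.default_rng(seed)
            rates = np.clip(clean + rng.normal(0, 5.0, i.size), 0.0, None)
            fit = fit_fi_sigmoid(FICurve(i, rates, 800.0))
            assert abs(fit.xhalf - 150.0) < 12.5

    def test_translation_equivariance(self):
        i = np.arange(25.0, 301.0, 25.0)
        curve = FICurve(i, sigmoid(i, 250.0, 150.0, 25.0), 800.0)
        shifted = FICurve(i - 50.0, curve.rates, 800.0)
        assert fit_fi_sigmoid(shifted).xhalf == pytest.approx(
            fit_fi_sigmoid(curve).xhalf - 50.0, abs=0.5
        )

    def test_rate_scaling_equivariance(self):
        i = np.arange(25.0, 301.0, 25.0)
        curve = FICurve(i, sigmoid(i, 250.0, 150.0, 25.0), 800.0)
        doubled = FICurve(i, 2.0 * curve.rates, 800.0)
        fit, fit2 = fit_fi_sigmoid(curve), fit_fi_sigmoid(doubled)
        assert fit2.max_rate == pytest.approx(2.0 * fit.max_rate, rel=0.01)
        assert fit2.xhalf == pytest.approx(fit.xhalf, abs=0.5)

    def test_all_zero_rates_refused(self):
        with pytest.raises(ValueError, match="nonzero"):
            fit_fi_sigmoid(FICurve(np.arange(4.0), np.zeros(4), 800.0))

    def test_four_parameter_variant_fits_offset(self):
        i = np.arange(25.0, 301.0, 25.0)
        curve = FICurve(i, 10.0 + sigmoid(i, 200.0, 150.0, 25.0), 800.0)
        fit = fit_fi_sigmoid(curve, with_offset=True)
        assert fit.offset == pytest.approx(10.0, abs=2.0)
        assert fit.xhalf == pytest.approx(150.0, abs=5.0)


class TestRheobase:
    def test_first_spiking_amplitude(self):
        sweeps = []
        for amp in (100.0, 125.0, 150.0):
            times = [60.0] if amp >= 125.0 else []
            sw = make_triangle_spike_sweep(times, duration_ms=140.0, onset_ms=20.0,
                                           step_pa=amp)
            sweeps.append(sw)
        rb = rheobase(sweeps)
        assert rb.current_pa == 125.0
        assert rb.resolution_pa == 25.0

    def test_planted_shift_recovered_at_protocol_resolution(self, fs):
        drug = apply_effects(fs, 2.5, -2.0, -25.0)
        proto = default_protocols(theoretical_rheobase(fs))["rheobase_fine"]
        rb_base = rheobase(simulate_current_clamp(fs, proto))
        rb_drug = rheobase(simulate_current_clamp(drug, proto))
        assert rb_drug.current_pa - rb_base.current_pa == pytest.approx(-25.0, abs=5.0)

    def test_all_sweeps_spiking_flagged_unbounded(self):
        sweeps = [make_triangle_spike_sweep([60.0], duration_ms=140.0, onset_ms=20.0,
                                            step_pa=amp) for amp in (50.0, 75.0)]
        rb = rheobase(sweeps)
        assert rb.current_pa == 50.0 and rb.unbounded_below

    def test_no_spiking_sweep_undefined(self):
        sweeps = [make_triangle_spike_sweep([], duration_ms=140.0, step_pa=amp)
                  for amp in (50.0, 75.0)]
        with pytest.warns(UserWarning, match="undefined"):
            rb = rheobase(sweeps)
        assert not rb.defined


class TestSelectRheobasePlus:
    @staticmethod
    def _family(amps):
        return [make_triangle_spike_sweep([60.0], duration_ms=140.0, onset_ms=20.0,
                                          step_pa=a) for a in amps]

    def test_exact_target_selected(self):
        sweeps = self._family(np.arange(25.0, 301.0, 25.0))
        assert select_rheobase_plus(sweeps, 100.0).stimulus.amplitude == 150.0

    def test_nearest_with_tie_broken_upward(self):
        sweeps = self._family(np.arange(25.0, 301.0, 25.0))
        with pytest.warns(UserWarning, match="nearest"):
            picked = select_rheobase_plus(sweeps, 112.5)  # target 162.5: tie 150/175
        assert picked.stimulus.amplitude == 175.0

    def test_no_sweep_near_target_raises(self):
        sweeps = self._family([25.0, 50.0])
        with pytest.raises(ValueError, match="within one step"):
            select_rheobase_plus(sweeps, 100.0)


class TestRampThreshold:
    def test_planted_initiation_voltage_on_ramp(self, fs, protocols):
        sw = simulate_current_clamp(fs, protocols["ramp"])[0]
        thr = threshold_from_ramp(sw)
        assert thr == pytest.approx(fs.spike_initiation_threshold, abs=1.0)

    def test_planted_threshold_shift_recovered(self, fs, protocols):
        drug = apply_effects(fs, 0.0, -2.0, None)
        a = threshold_from_ramp(simulate_current_clamp(fs, protocols["ramp"])[0])
        b = threshold_from_ramp(simulate_current_clamp(drug, protocols["ramp"])[0])
        assert b - a == pytest.approx(-2.0, abs=0.5)

    def test_spike_free_ramp_flagged(self, fs, protocols):
        quiet = fs_preset(spike_initiation_threshold=100.0, spike_peak=150.0,
                          reset_potential=90.0)
        sw = simulate_current_clamp(quiet, protocols["ramp"])[0]
        with pytest.warns(UserWarning, match="no spikes"):
            assert threshold_from_ramp(sw) is None


class TestClassification:
    @staticmethod
    def _curve(max_rate):
        i = np.arange(25.0, 301.0, 25.0)
        return FICurve(i, np.linspace(0.0, max_rate, i.size), 800.0)

    def test_fast_low_adaptation_is_fs(self):
        assert classify_cell(self._curve(250.0), 1.1).label == "FS"

    def test_slow_high_adaptation_is_pyr(self):
        assert classify_cell(self._curve(80.0), 3.0).label == "PYR"

    def test_contradictory_evidence_unclassified(self):
        cls = classify_cell(self._curve(250.0), 3.0)
        assert cls.label == "unclassified" and "conflict" in cls.evidence

    def test_fluorescence_disagreement_flagged_not_overridden(self):
        cls = classify_cell(self._curve(250.0), 1.1, fluorescence_label="PYR")
        assert cls.label == "FS" and cls.conflict

    def test_generator_presets_classified_correctly(self, fs_fi_sweeps, pyr_fi_sweeps):
        from fsinephys import adaptation_ratio

        for sweeps, expected in ((fs_fi_sweeps, "FS"), (pyr_fi_sweeps, "PYR")):
            curve = build_fi_curve(sweeps)
            top = sweeps[-1]
            times = [top.time_ms[p] for p in detect_spikes(top)]
            assert classify_cell(curve, adaptation_ratio(times)).label == expected
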