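"""Single-AP feature estimators against analytic and generator oracles."""

import numpy as np
import pytest

from fsinephys import (
    DetectionConfig,
    FeatureConfig,
    Stimulus,
    Sweep,
    adaptation_ratio,
    ap_amplitude_halfwidth,
    ap_fahp,
    ap_threshold,
    detect_spikes,
    extract_ap_features,
    fs_preset,
    max_dvdt,
    simulate_current_clamp,
    spike_waveform_truth,
)
from fsinephys.synthetic_data import ProtocolSpec

from conftest import make_triangle_spike_sweep


def flat_sweep(level=-70.0, duration=200.0, khz=20.0):
    n = int(round(duration * khz)) + 1
    return Sweep(np.arange(n) / khz, np.full(n, level), "mV", khz,
                 Stimulus(0.0, 10.0, duration - 20.0, "step"))


class TestDetector:
    def test_flat_trace_has_no_events(self):
        assert detect_spikes(flat_sweep()) == []

    def test_counts_and_locates_planted_spikes(self):
        times = [50.0, 80.0, 120.0]
        sw = make_triangle_spike_sweep(times)
        peaks = detect_spikes(sw)
        assert len(peaks) == 3
        for p, ts in zip(peaks, times):
            assert abs(sw.time_ms[p] - ts) <= sw.dt_ms

    def test_close_spikes_resolved_when_separation_allows(self):
        sw = make_triangle_spike_sweep([100.0, 102.0], base_width_ms=0.8)
        assert len(detect_spikes(sw, DetectionConfig(min_separation_ms=2.0))) == 2
        assert len(detect_spikes(sw, DetectionConfig(min_separation_ms=3.0))) == 1

    def test_dvdt_detector_agrees_on_planted_spikes(self):
        sw = make_triangle_spike_sweep([50.0, 80.0])
        crossing = detect_spikes(sw, DetectionConfig(method="crossing"))
        dvdt = detect_spikes(sw, DetectionConfig(method="dvdt", dvdt_threshold=50.0))
        assert len(crossing) == len(dvdt) == 2

    def test_current_sweep_rejected(self):
        sw = flat_sweep()
        sw.units = "pA"
        with pytest.raises(ValueError, match="voltage"):
            detect_spikes(sw)


class TestThreshold:
    def test_planted_initiation_voltage_recovered(self, fs, fs_fi_sweeps):
        sw = fs_fi_sweeps[-1]
        for p in detect_spikes(sw)[2:6]:
            thr = ap_threshold(sw, p)
            assert thr.voltage == pytest.approx(
                fs.spike_initiation_threshold, abs=1.0
            )
            assert thr.time_ms < sw.time_ms[p]

    def test_brute_force_third_difference_agrees_on_noiseless_trace(self, fs_fi_sweeps):
        # independent oracle: raw third differences on the noiseless trace
        sw = fs_fi_sweeps[-1]
        p = detect_spikes(sw)[3]
        cfg = FeatureConfig()
        start = p - int(round(cfg.search_window_ms * sw.sampling_khz))
        seg = sw.values[start : p + 1]
        d3 = np.diff(seg, n=3)
        oracle_v = seg[int(np.argmax(d3))]
        thr = ap_threshold(sw, p, cfg)
        assert thr.voltage == pytest.approx(oracle_v, abs=0.5)

    def test_constant_third_derivative_breaks_tie_at_window_start(self):
        # pure cubic upstroke built from exactly representable values
        # (integers scaled by a power of two), so its third differences are
        # exactly constant and the earliest-maximum tie-break is exercised
        khz = 20.0
        n = 2001
        t = np.arange(n) / khz
        i0 = 1800
        idx = np.arange(n)
        v = np.where(idx >= i0, (idx - i0).astype(float) ** 3 * 2.0**-10, 0.0) - 70.0
        sw = Sweep(t, v, "mV", khz, Stimulus(0, 10, 80, "step"))
        peak = n - 1
        cfg = FeatureConfig(search_window_ms=3.0, smooth=False)
        thr = ap_threshold(sw, peak, cfg)
        assert thr.index == peak - int(round(3.0 * khz))

    def test_window_truncated_by_sweep_start_raises(self):
        sw = make_triangle_spike_sweep([1.0])
        p = detect_spikes(sw)[0]
        with pytest.raises(ValueError, match="truncated"):
            ap_threshold(sw, p, FeatureConfig(search_window_ms=5.0))

    def test_noise_robustness_with_smoothing(self, fs):
        """0.2 mV noise moves the threshold estimate < 2 mV from noiseless."""
        proto = ProtocolSpec("step_family", (250.0,), 50.0, 200.0, 300.0, 20.0)
        clean = simulate_current_clamp(fs, proto, noise_sd=0.0)[0]
        p = detect_spikes(clean)[2]
        v_clean = ap_threshold(clean, p).voltage
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            noisy = Sweep(clean.time_ms, clean.values + rng.normal(0, 0.2, clean.n_samples),
                          "mV", clean.sampling_khz, clean.stimulus)
            pk = detect_spikes(noisy)[2]
            errs.append(abs(ap_threshold(noisy, pk).voltage - v_clean))
        assert np.max(errs) < 2.0


class TestAmplitudeHalfWidth:
    def test_triangle_geometry_exact(self):
        # triangle: base -70, peak +20, base width 1 ms -> with threshold -40
        # amplitude 60 mV and half-width 0.5 ms by similar triangles
        sw = make_triangle_spike_sweep([100.0], baseline_mv=-70.0, peak_mv=20.0,
                                       base_width_ms=1.0, khz=100.0)
        p = detect_spikes(sw)[0]
        amp, hw = ap_amplitude_halfwidth(sw, p, threshold=-40.0)
        assert amp == pytest.approx(60.0, abs=1e-6)
        # half level -10 mV; triangle crosses it 2/3 of the way up each side
        assert hw == pytest.approx(1.0 / 3.0, abs=sw.dt_ms)

    def test_degenerate_peak_at_threshold_rejected(self):
        sw = make_triangle_spike_sweep([100.0])
        p = detect_spikes(sw)[0]
        with pytest.raises(ValueError, match="degenerate"):
            ap_amplitude_halfwidth(sw, p, threshold=float(sw.values[p]))

    def test_missing_falling_crossing_raises(self):
        khz = 20.0
        t = np.arange(0, 50.0, 1 / khz)
        v = np.where(t < 25.0, -70.0, 10.0)  # steps up and stays up
        sw = Sweep(t, v, "mV", khz, Stimulus(0, 5, 40, "step"))
        with pytest.raises(ValueError, match="falling"):
            ap_amplitude_halfwidth(sw, int(np.argmax(v)), threshold=-40.0)


class TestFAHPAndDvdt:
    def test_fahp_is_threshold_minus_trough(self):
        khz = 20.0
        t = np.arange(0, 40.0, 1 / khz)
        v = np.full(t.size, -50.0)
        v[(t >= 20.0) & (t < 20.5)] = 10.0    # spike
        v[(t >= 20.5) & (t < 25.0)] = -55.0   # trough
        sw = Sweep(t, v, "mV", khz, Stimulus(0, 5, 30, "step"))
        p = int(np.argmax(v))
        assert ap_fahp(sw, p, threshold=-40.0) == pytest.approx(15.0)

    def test_no_trough_below_threshold_flags_nonpositive(self):
        khz = 20.0
        t = np.arange(0, 40.0, 1 / khz)
        v = -70.0 + t  # monotonically rising: no trough dips below threshold
        sw = Sweep(t, v, "mV", khz, Stimulus(0, 5, 30, "step"))
        assert ap_fahp(sw, 400, threshold=-55.0) <= 0.0

    def test_linear_rise_slope(self):
        khz = 20.0
        t = np.arange(0, 20.0, 1 / khz)
        v = np.where(t < 10.0, -70.0, np.minimum(-70.0 + 200.0 * (t - 10.0), 30.0))
        sw = Sweep(t, v, "mV", khz, Stimulus(0, 2, 16, "step"))
        peak = int(np.argmax(v))
        thr_idx = int(np.searchsorted(t, 10.0))
        assert max_dvdt(sw, peak, thr_idx) == pytest.approx(200.0, rel=0.01)


class TestAdaptationRatio:
    def test_regular_train_is_unity(self):
        assert adaptation_ratio([10, 20, 30, 40]) == pytest.approx(1.0)

    def test_growing_isis(self):
        assert adaptation_ratio([0, 10, 30, 70]) == pytest.approx(4.0)

    def test_fewer_than_three_spikes_undefined(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(adaptation_ratio([10, 20]))


class TestGeneratorOracle:
    """All five features recover planted values; estimates converge with rate."""

    RATES = (10.0, 20.0, 50.0)

    @staticmethod
    def _measure(params, khz):
        proto = ProtocolSpec("step_family", (250.0,), 50.0, 300.0, 400.0, khz)
        sw = simulate_current_clamp(params, proto, noise_sd=0.0)[0]
        feats = extract_ap_features(sw)
        mid = feats[2:-1]  # steady-state spikes away from onset
        return {
            "threshold": np.mean([f.threshold for f in mid]),
            "amplitude": np.mean([f.amplitude for f in mid]),
            "half_width": np.mean([f.half_width for f in mid]),
            "fahp": np.mean([f.fahp for f in mid]),
            "max_dvdt": np.mean([f.max_dvdt for f in mid]),
        }

    def test_planted_values_recovered_at_20khz(self, fs):
        truth = spike_waveform_truth(fs)
        got = self._measure(fs, 20.0)
        assert got["threshold"] == pytest.approx(truth["threshold"], abs=1.0)
        assert got["amplitude"] == pytest.approx(truth["amplitude"], abs=1.0)
        assert got["half_width"] == pytest.approx(truth["half_width"], abs=1 / 20.0)
        assert got["fahp"] == pytest.approx(truth["fahp"], abs=0.5)
        assert got["max_dvdt"] == pytest.approx(truth["max_dvdt"], rel=0.05)

    def test_estimates_converge_with_sampling_rate(self, fs):
        truth = spike_waveform_truth(fs)
        errs = {khz: self._measure(fs, khz) for khz in self.RATES}
        for feat in ("threshold", "half_width", "fahp", "max_dvdt"):
            e10 = abs(errs[10.0][feat] - truth[feat])
            e50 = abs(errs[50.0][feat] - truth[feat])
            assert e50 <= e10 + 1e-9, feat

    def test_detector_and_feature_counts_agree(self, fs_fi_sweeps):
        for sw in fs_fi_sweeps:
            feats = extract_ap_features(sw)
            assert len(feats) == len(detect_spikes(sw))
            for f in feats:
                assert f.threshold_time < f.peak_time
                assert f.amplitude > 0 and f.half_width > 0
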