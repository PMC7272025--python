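"""Generator contracts: determinism, leak-circuit physics, phenotype behavior,
EPSC statistics, and paired-cohort ground truth."""

import numpy as np
import pytest

from fsinephys import (
    DEFAULT_FSIN_EFFECTS,
    PlantedEffects,
    adaptation_ratio,
    apply_effects,
    detect_spikes,
    fs_preset,
    generate_epsc_series,
    input_resistance_vc,
    pyr_preset,
    simulate_current_clamp,
    simulate_vclamp_step,
    theoretical_rheobase,
)
from fsinephys.synthetic_data import ProtocolSpec, build_paired_cohort, default_protocols


def step_protocol(amplitudes, duration=500.0, onset=100.0, khz=20.0, tail=200.0):
    return ProtocolSpec("step_family", tuple(amplitudes), onset, duration,
                        onset + duration + tail, khz)


class TestCurrentClamp:
    def test_zero_step_is_flat_at_rest(self, fs):
        sw = simulate_current_clamp(fs, step_protocol([0.0]), noise_sd=0.0)[0]
        assert np.allclose(sw.values, fs.resting_potential)

    def test_subthreshold_deflection_obeys_ohms_law(self, fs):
        # leak-only circuit: steady-state deflection is I/gL exactly
        sw = simulate_current_clamp(fs, step_protocol([-50.0]))[0]
        i0, i1 = sw.stimulus_window()
        deflection = sw.values[i1 - 1] - fs.resting_potential
        assert deflection == pytest.approx(-50.0 / fs.leak_conductance, rel=5e-3)

    def test_subthreshold_decay_is_single_exponential_with_tau_c_over_gl(self, fs):
        params = fs_preset(fast_fraction=0.0)
        sw = simulate_current_clamp(params, step_protocol([-50.0]))[0]
        off = sw.index_at(600.0)
        t = sw.time_ms[off:] - sw.time_ms[off]
        d = sw.values[off:] - params.resting_potential
        keep = d < -0.05  # fit before the deflection reaches the noise floor
        slope = np.polyfit(t[keep], np.log(-d[keep]), 1)[0]
        assert -1.0 / slope == pytest.approx(params.tau_m, rel=0.01)

    def test_fs_preset_fires_above_200hz_at_top_step(self, fs_fi_sweeps):
        sw = fs_fi_sweeps[-1]  # 300 pA, 800 ms
        rate = len(detect_spikes(sw)) / 0.8
        assert rate > 200.0

    def test_fs_adaptation_is_minimal(self, fs_fi_sweeps):
        sw = fs_fi_sweeps[-1]
        times = [sw.time_ms[k] for k in detect_spikes(sw)]
        assert adaptation_ratio(times) < 1.3

    def test_pyr_adaptation_is_pronounced(self, pyr_fi_sweeps):
        sw = pyr_fi_sweeps[-1]
        times = [sw.time_ms[k] for k in detect_spikes(sw)]
        assert adaptation_ratio(times) > 2.0

    def test_identical_seed_gives_identical_arrays(self, fs):
        proto = step_protocol([-50.0, 100.0, 300.0])
        a = simulate_current_clamp(fs, proto, noise_sd=0.3, seed=42)
        b = simulate_current_clamp(fs, proto, noise_sd=0.3, seed=42)
        for x, y in zip(a, b):
            assert np.array_equal(x.values, y.values)

    def test_vclamp_kind_rejected(self, fs, protocols):
        with pytest.raises(ValueError, match="current-clamp"):
            simulate_current_clamp(fs, protocols["vclamp"])

    def test_empty_protocol_rejected(self):
        with pytest.raises(ValueError, match="no step amplitudes"):
            step_protocol([])

    def test_unordered_amplitudes_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            step_protocol([100.0, 50.0])


class TestVClamp:
    @pytest.mark.parametrize("rin,expected_pa", [(100.0, 100.0), (200.0, 50.0)])
    def test_steady_state_current_is_ohmic(self, rin, expected_pa):
        # long step so the capacitive transient has fully settled
        proto = ProtocolSpec("vclamp_step", (10.0,), 100.0, 400.0, 600.0, 10.0)
        sw = simulate_vclamp_step(rin_mohm=rin, cm_pf=100.0, step_mv=10.0,
                                  protocol=proto)
        i0, i1 = sw.stimulus_window()
        assert sw.values[i1 - 1] == pytest.approx(expected_pa, rel=1e-3)

    def test_transient_time_constant_is_rc(self):
        sw = simulate_vclamp_step(rin_mohm=100.0, cm_pf=100.0, step_mv=10.0)
        i0, i1 = sw.stimulus_window()
        t = sw.time_ms[i0:i1] - sw.time_ms[i0]
        excess = sw.values[i0:i1] - 100.0  # transient above the 100 pA steady state
        keep = excess > 1.0
        slope = np.polyfit(t[keep], np.log(excess[keep]), 1)[0]
        assert -1.0 / slope == pytest.approx(10.0, rel=0.02)  # tau = R*C = 10 ms

    def test_recovered_by_input_resistance_vc(self):
        sw = simulate_vclamp_step(rin_mohm=120.0, cm_pf=80.0)
        assert input_resistance_vc(sw) == pytest.approx(120.0, rel=0.01)

    def test_zero_step_rejected(self):
        with pytest.raises(ValueError, match="nonzero"):
            simulate_vclamp_step(rin_mohm=100.0, cm_pf=100.0, step_mv=0.0)


class TestEPSCSeries:
    def test_identity_factor_keeps_all_peaks_at_base(self):
        s = generate_epsc_series(120.0, noise_cv=0.0, potentiation_factor=1.0,
                                 render_sweeps=False)
        peaks = [e.planted_amplitude_pa for e in s.events]
        assert np.allclose(peaks, 120.0)

    def test_planted_factor_scales_drug_window_exactly(self):
        s = generate_epsc_series(100.0, noise_cv=0.0, potentiation_factor=1.83,
                                 render_sweeps=False)
        base = [e.planted_amplitude_pa for e in s.events if e.timestamp_s < s.drug_onset_s]
        drug = [e.planted_amplitude_pa for e in s.events if e.timestamp_s >= s.drug_onset_s]
        assert np.mean(drug) / np.mean(base) == pytest.approx(1.83, abs=1e-12)

    def test_lognormal_noise_preserves_mean_ratio(self):
        # Monte-Carlo at ~10,000 events: drug/baseline mean ratio within 3 SEM of 2
        s = generate_epsc_series(
            100.0, noise_cv=0.1, potentiation_factor=2.0, seed=3,
            stim_interval_s=0.1, baseline_duration_s=500.0, drug_duration_s=500.0,
            render_sweeps=False,
        )
        base = np.array([e.planted_amplitude_pa for e in s.events
                         if e.timestamp_s < s.drug_onset_s])
        drug = np.array([e.planted_amplitude_pa for e in s.events
                         if e.timestamp_s >= s.drug_onset_s])
        ratio = drug.mean() / base.mean()
        sem = ratio * np.sqrt(
            base.std(ddof=1) ** 2 / (base.mean() ** 2 * base.size)
            + drug.std(ddof=1) ** 2 / (drug.mean() ** 2 * drug.size)
        )
        assert abs(ratio - 2.0) < 3 * sem

    def test_rendered_sweep_peak_matches_planted(self):
        s = generate_epsc_series(120.0, noise_cv=0.0, potentiation_factor=1.0)
        ev = s.events[0]
        assert np.min(ev.sweep.values) == pytest.approx(-120.0)

    def test_negative_base_amplitude_rejected(self):
        with pytest.raises(ValueError, match="magnitude"):
            generate_epsc_series(-5.0)


class TestApplyEffects:
    def test_voltage_shifts_applied_directly(self, fs):
        drug = apply_effects(fs, 2.5, -2.0, None)
        assert drug.resting_potential == fs.resting_potential + 2.5
        assert drug.spike_initiation_threshold == fs.spike_initiation_threshold - 2.0
        assert drug.fahp_depth == pytest.approx(fs.fahp_depth)

    def test_explicit_rheobase_shift_honored_exactly(self, fs):
        drug = apply_effects(fs, 2.5, -2.0, -25.0)
        assert theoretical_rheobase(drug) == pytest.approx(
            theoretical_rheobase(fs) - 25.0
        )

    def test_implied_rheobase_shift_without_explicit_target(self, fs):
        drug = apply_effects(fs, 2.5, -2.0, None)
        implied = fs.leak_conductance * (-2.0 - 2.5)
        assert theoretical_rheobase(drug) - theoretical_rheobase(fs) == pytest.approx(implied)


class TestPairedCohort:
    def test_degenerate_variability_plants_group_means_exactly(self):
        effects = PlantedEffects(delta_rmp=2.5, delta_threshold=-2.0,
                                 delta_rheobase=-25.0, epsc_potentiation_factor=1.83)
        cells, manifest = build_paired_cohort(
            6, effects=effects, protocols={}, noise_sd=0.0, epsc_noise_cv=0.0,
            cell_rmp_jitter_sd=0.0, render_epsc_sweeps=False, seed=0,
        )
        for c in manifest.cells:
            assert c.realized_delta_rmp == 2.5
            assert c.realized_delta_threshold == -2.0
            assert c.realized_delta_rheobase == pytest.approx(-25.0)
            assert c.realized_epsc_factor == 1.83

    def test_planted_rmp_shift_realized_within_3_sem(self):
        effects = PlantedEffects(delta_rmp=2.5, sd_rmp=1.0)
        _, manifest = build_paired_cohort(
            8, effects=effects, protocols={}, noise_sd=0.0,
            render_epsc_sweeps=False, seed=1,
        )
        realized = [c.realized_delta_rmp for c in manifest.cells]
        sem = np.std(realized, ddof=1) / np.sqrt(len(realized))
        assert abs(np.mean(realized) - 2.5) < 3 * sem

    def test_cohort_requires_two_cells(self):
        with pytest.raises(ValueError, match="at least 2"):
            build_paired_cohort(1, protocols={})

    def test_same_seed_same_cohort(self):
        kw = dict(protocols={"subthreshold": default_protocols()["subthreshold"]},
                  noise_sd=0.3, render_epsc_sweeps=False)
        a, _ = build_paired_cohort(2, seed=9, **kw)
        b, _ = build_paired_cohort(2, seed=9, **kw)
        for ca, cb in zip(a, b):
            for cond in ("baseline", "drug"):
                for sa, sb in zip(ca.sweeps[cond]["subthreshold"],
                                  cb.sweeps[cond]["subthreshold"]):
                    assert np.array_equal(sa.values, sb.values)
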