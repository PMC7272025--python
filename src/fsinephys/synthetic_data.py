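"""Synthetic patch-clamp data with planted ground truth.

Every downstream stage of the pipeline (AP features, passive properties,
F-I analysis, EPSC potentiation, paired statistics) is validated by
parameter recovery on data from this module.  The neuron model is an
adaptive leaky integrate-and-fire cell whose action potentials are rendered
as stereotyped waveforms spliced into the trace at the moment the membrane
crosses a planted initiation voltage: the spike shape (peak, rise/fall
times, afterhyperpolarization trough) is therefore known exactly, which
gives the waveform-feature estimators an analytic oracle.

Units throughout: mV, pA, ms, nS, pF, MOhm, kHz.  With these units
dV/dt [mV/ms] = I [pA] / C [pF] and tau [ms] = C [pF] / gL [nS].

Conditions emulated:

* fast-spiking interneuron (FS) presets sustain > 200 Hz firing at the top
  of the 25-300 pA step range with near-unity spike-frequency adaptation;
* pyramidal (PYR) presets adapt strongly (last/first inter-spike interval
  ratio well above 2);
* evoked-EPSC series: 10 min baseline followed by 15 min of drug, event
  amplitudes multiplied by a planted potentiation factor after drug onset;
* paired baseline/drug cohorts with planted per-cell effect sizes
  (resting-potential shift, threshold shift, rheobase shift, EPSC factor).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import brentq

from .epsc_analysis import EPSCEvent, EPSCSeries
from .trace_features import Stimulus, Sweep

__all__ = [
    "NeuronModelParams",
    "ProtocolSpec",
    "PlantedEffects",
    "CellTruth",
    "GroundTruthManifest",
    "fs_preset",
    "pyr_preset",
    "DEFAULT_FSIN_EFFECTS",
    "NULL_EFFECTS",
    "default_protocols",
    "theoretical_rheobase",
    "spike_waveform_truth",
    "apply_effects",
    "simulate_current_clamp",
    "simulate_vclamp_step",
    "generate_epsc_series",
    "build_paired_cohort",
    "generate_paired_cohort",
]

MAX_INTEGRATION_STEP_MS = 0.05  # fixed-step scheme refines below this


# ---------------------------------------------------------------------------
# model and protocol types


@dataclass(frozen=True)
class NeuronModelParams:
    """Adaptive leaky integrate-and-fire cell with a stereotyped spike shape.

    ``sharpness`` is the exponential spike-initiation slope factor of the
    underlying AdEx formulation; the rendered upstroke begins exactly at
    ``spike_initiation_threshold``, so that voltage is the planted AP
    threshold.  ``adaptation_increment`` (pA) is added to the adaptation
    current at each spike and decays with ``adaptation_time_constant``.
    The optional fast charging component (``tau_fast_ms``,
    ``fast_fraction``) emulates dendritic charge redistribution and shapes
    brief-pulse decays into a genuine double exponential.
    """

    membrane_capacitance: float          # pF
    leak_conductance: float              # nS
    resting_potential: float             # mV
    spike_initiation_threshold: float    # mV
    sharpness: float                     # mV
    reset_potential: float               # mV (also the fAHP trough)
    refractory_period: float             # ms
    adaptation_increment: float          # pA per spike
    adaptation_time_constant: float      # ms
    phenotype_label: Literal["FS", "PYR"]
    spike_peak: float = 25.0             # mV
    spike_rise_ms: float = 0.4
    spike_fall_ms: float = 0.4
    tau_fast_ms: float = 0.0
    fast_fraction: float = 0.0
    tonic_current: float = 0.0           # pA

    def __post_init__(self) -> None:
        if self.membrane_capacitance <= 0 or self.leak_conductance <= 0:
            raise ValueError("capacitance and leak conductance must be positive")
        if self.reset_potential >= self.spike_initiation_threshold:
            raise ValueError("reset potential must lie below spike threshold")
        if self.spike_peak <= self.spike_initiation_threshold:
            raise ValueError("spike peak must lie above threshold")
        if self.adaptation_time_constant <= 0:
            raise ValueError("adaptation time constant must be positive")
        if not 0.0 <= self.fast_fraction < 1.0:
            raise ValueError("fast_fraction must be in [0, 1)")

    @property
    def tau_m(self) -> float:
        """Membrane time constant C/gL (ms)."""
        return self.membrane_capacitance / self.leak_conductance

    @property
    def input_resistance_mohm(self) -> float:
        """1/gL expressed in MOhm (mV per pA is GOhm; x1000 for MOhm)."""
        return 1000.0 / self.leak_conductance

    @property
    def fahp_depth(self) -> float:
        return self.spike_initiation_threshold - self.reset_potential


def fs_preset(**overrides) -> NeuronModelParams:
    """Fast-spiking interneuron: small tau, weak adaptation, thin spikes."""
    base = dict(
        membrane_capacitance=48.0,
        leak_conductance=6.0,
        resting_potential=-70.0,
        spike_initiation_threshold=-45.0,
        sharpness=1.0,
        reset_potential=-58.0,
        refractory_period=1.2,
        adaptation_increment=2.0,
        adaptation_time_constant=40.0,
        phenotype_label="FS",
        spike_peak=25.0,
        spike_rise_ms=0.4,
        spike_fall_ms=0.4,
        tau_fast_ms=0.6,
        fast_fraction=0.1,
    )
    base.update(overrides)
    return NeuronModelParams(**base)


def pyr_preset(**overrides) -> NeuronModelParams:
    """Pyramidal cell: slow tau, strong spike-frequency adaptation, broad spikes."""
    base = dict(
        membrane_capacitance=100.0,
        leak_conductance=5.0,
        resting_potential=-72.0,
        spike_initiation_threshold=-42.0,
        sharpness=2.0,
        reset_potential=-55.0,
        refractory_period=2.5,
        adaptation_increment=60.0,
        adaptation_time_constant=150.0,
        phenotype_label="PYR",
        spike_peak=35.0,
        spike_rise_ms=0.5,
        spike_fall_ms=0.9,
        tau_fast_ms=1.2,
        fast_fraction=0.1,
    )
    base.update(overrides)
    return NeuronModelParams(**base)


_PROTOCOL_KINDS = (
    "step_family",
    "rheobase_fine",
    "vclamp_step",
    "brief_pulse",
    "ramp",
    "epsc_train",
)


@dataclass(frozen=True)
class ProtocolSpec:
    """A stimulation protocol: ordered step amplitudes plus timing."""

    protocol_kind: str
    step_amplitudes: tuple[float, ...]
    step_onset: float        # ms
    step_duration: float     # ms
    sweep_duration: float    # ms
    sampling_rate: float     # kHz

    def __post_init__(self) -> None:
        if self.protocol_kind not in _PROTOCOL_KINDS:
            raise ValueError(f"unknown protocol kind {self.protocol_kind!r}")
        if self.step_onset + self.step_duration > self.sweep_duration + 1e-9:
            raise ValueError("stimulus must end within the sweep")
        if self.sampling_rate < 10.0:
            raise ValueError(
                "sampling rate below 10 kHz is too sparse for third-derivative "
                "threshold estimation"
            )
        amps = self.step_amplitudes
        if len(amps) == 0:
            raise ValueError("protocol has no step amplitudes")
        if any(b <= a for a, b in zip(amps, amps[1:])):
            raise ValueError("step amplitudes must be strictly increasing")

    @property
    def step_size(self) -> float:
        amps = self.step_amplitudes
        return amps[1] - amps[0] if len(amps) > 1 else 0.0


def default_protocols(fine_center_pa: float = 150.0) -> dict[str, ProtocolSpec]:
    """The standard per-cell protocol battery.

    Two step families coexist: 500 ms steps from -100 to +300 pA in 50 pA
    increments for characterization, and 800 ms steps from 25 to 300 pA in
    25 pA increments for firing output; plus the -50..+20 pA/10 pA
    subthreshold family, a 5 pA fine grid around ``fine_center_pa`` for
    rheobase, a -400 pA/1 ms pulse for tau, a 10 mV voltage-clamp step, and
    a current ramp.
    """
    lo = 5.0 * math.floor((fine_center_pa - 60.0) / 5.0)
    hi = 5.0 * math.ceil((fine_center_pa + 40.0) / 5.0)
    fine = tuple(np.arange(lo, hi + 1e-9, 5.0))
    return {
        "subthreshold": ProtocolSpec(
            "step_family", tuple(np.arange(-50.0, 20.0 + 1e-9, 10.0)),
            100.0, 500.0, 800.0, 20.0,
        ),
        "characterization": ProtocolSpec(
            "step_family", tuple(np.arange(-100.0, 300.0 + 1e-9, 50.0)),
            100.0, 500.0, 800.0, 20.0,
        ),
        "fi": ProtocolSpec(
            "step_family", tuple(np.arange(25.0, 300.0 + 1e-9, 25.0)),
            100.0, 800.0, 1100.0, 20.0,
        ),
        "rheobase_fine": ProtocolSpec(
            "rheobase_fine", fine, 100.0, 500.0, 700.0, 20.0,
        ),
        "brief_pulse": ProtocolSpec(
            "brief_pulse", (-400.0,), 20.0, 1.0, 150.0, 20.0,
        ),
        "vclamp": ProtocolSpec(
            "vclamp_step", (10.0,), 100.0, 150.0, 350.0, 10.0,
        ),
        "ramp": ProtocolSpec(
            "ramp", (400.0,), 100.0, 500.0, 700.0, 20.0,
        ),
    }


# ---------------------------------------------------------------------------
# planted effects


@dataclass(frozen=True)
class PlantedEffects:
    """Group-level drug effects planted per cell (Gaussian between-cell spread).

    ``delta_rheobase`` may be None, in which case the rheobase shift follows
    from the planted voltage shifts (in a leaky integrator the rheobase is
    gL*(threshold - rest)); when given, the drug-condition leak conductance
    is solved to honor it exactly.
    """

    delta_rmp: float = 0.0                 # mV
    delta_threshold: float = 0.0           # mV
    delta_rheobase: float | None = None    # pA
    epsc_potentiation_factor: float = 1.0
    sd_rmp: float = 0.0
    sd_threshold: float = 0.0
    sd_rheobase: float = 0.0
    sd_epsc_factor: float = 0.0

    def __post_init__(self) -> None:
        if self.epsc_potentiation_factor <= 0:
            raise ValueError("EPSC potentiation factor must be positive")
        for name in ("sd_rmp", "sd_threshold", "sd_rheobase", "sd_epsc_factor"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


#: Shipped default drug effects for the FSIN group: depolarized rest,
#: lowered threshold and rheobase, 1.83x EPSC potentiation (an 83% group
#: increase).  Between-cell SDs model biological heterogeneity of the
#: response, separate from trace noise.
DEFAULT_FSIN_EFFECTS = PlantedEffects(
    delta_rmp=2.5,
    delta_threshold=-2.0,
    delta_rheobase=-25.0,
    epsc_potentiation_factor=1.83,
    sd_rmp=1.0,
    sd_threshold=0.5,
    sd_rheobase=10.0,
    sd_epsc_factor=0.10,
)

#: Null effects (the pyramidal group / type-I-error simulations).
NULL_EFFECTS = PlantedEffects()


def theoretical_rheobase(params: NeuronModelParams) -> float:
    """Smallest sustained current that drives the leak circuit to threshold (pA)."""
    return (
        params.leak_conductance
        * (params.spike_initiation_threshold - params.resting_potential)
        - params.tonic_current
    )


def apply_effects(
    params: NeuronModelParams,
    delta_rmp: float,
    delta_threshold: float,
    delta_rheobase: float | None,
) -> NeuronModelParams:
    """Drug-condition parameters realizing the planted shifts.

    Rest and threshold shift directly (the reset shifts with the threshold so
    the fAHP depth is preserved).  An explicit rheobase shift is honored by
    solving for the drug leak conductance, since gL*(V_T - V_rest) fixes the
    rheobase of a leaky integrator; the implied (small) input-resistance
    change is recorded in the manifest.
    """
    el = params.resting_potential + delta_rmp
    vt = params.spike_initiation_threshold + delta_threshold
    reset = params.reset_potential + delta_threshold
    peak = params.spike_peak + delta_threshold
    gl = params.leak_conductance
    if delta_rheobase is not None:
        target = theoretical_rheobase(params) + delta_rheobase
        drive = vt - el
        if drive <= 0:
            raise ValueError("drug threshold does not exceed drug rest")
        gl = (target + params.tonic_current) / drive
        if gl <= 0:
            raise ValueError("planted rheobase shift requires a negative leak")
    return replace(
        params,
        resting_potential=el,
        spike_initiation_threshold=vt,
        reset_potential=reset,
        spike_peak=peak,
        leak_conductance=gl,
    )


# ---------------------------------------------------------------------------
# spike waveform


def _smoothstep(x: np.ndarray) -> np.ndarray:
    return 3.0 * x**2 - 2.0 * x**3


def _render_spike_waveform(params: NeuronModelParams, dt_ms: float) -> np.ndarray:
    """Stereotyped AP sampled on the grid, from threshold to the fAHP trough.

    The rise is a cubic smoothstep from the planted initiation voltage to the
    peak: its second derivative jumps at onset, so the third time-derivative
    of the trace is sharply maximal at the planted threshold sample.
    """
    vt = params.spike_initiation_threshold
    peak = params.spike_peak
    reset = params.reset_potential
    tr, tf = params.spike_rise_ms, params.spike_fall_ms
    n = int(round((tr + tf) / dt_ms))
    t = np.arange(n + 1) * dt_ms
    wf = np.empty(n + 1)
    rising = t <= tr
    wf[rising] = vt + (peak - vt) * _smoothstep(t[rising] / tr)
    wf[~rising] = peak - (peak - reset) * _smoothstep(
        np.clip((t[~rising] - tr) / tf, 0.0, 1.0)
    )
    wf[-1] = reset  # land exactly on the trough
    return wf


def spike_waveform_truth(params: NeuronModelParams) -> dict[str, float]:
    """Analytic single-AP feature values implied by the rendered waveform."""
    vt = params.spike_initiation_threshold
    amp = params.spike_peak - vt
    drop = params.spike_peak - params.reset_potential
    # falling half-amplitude crossing: smoothstep fraction solving
    # 3y^2 - 2y^3 = (amp/2)/drop
    frac = (amp / 2.0) / drop
    y = brentq(lambda x: _smoothstep(np.asarray(x)) - frac, 0.0, 1.0)
    half_width = (params.spike_rise_ms / 2.0 - 0.0) + 0.0  # rising crossing at tr/2
    half_width = (params.spike_rise_ms + y * params.spike_fall_ms) - (
        params.spike_rise_ms / 2.0
    )
    return {
        "threshold": vt,
        "peak": params.spike_peak,
        "amplitude": amp,
        "half_width": half_width,
        "fahp": params.fahp_depth,
        "max_dvdt": 1.5 * amp / params.spike_rise_ms,  # smoothstep max slope
    }


# ---------------------------------------------------------------------------
# current-clamp simulation


def _stimulus_current(
    protocol: ProtocolSpec, amplitude: float, t_ms: np.ndarray
) -> np.ndarray:
    on, dur = protocol.step_onset, protocol.step_duration
    inside = (t_ms >= on) & (t_ms < on + dur)
    if protocol.protocol_kind == "ramp":
        ramp = np.clip((t_ms - on) / dur, 0.0, 1.0) * amplitude
        return np.where(inside, ramp, 0.0)
    return np.where(inside, amplitude, 0.0)


def _analytic_subthreshold(
    params: NeuronModelParams, protocol: ProtocolSpec, amplitude: float, t: np.ndarray
) -> np.ndarray:
    """Closed-form leak-circuit response to a subthreshold current step."""
    el = params.resting_potential + params.tonic_current / params.leak_conductance
    tau = params.tau_m
    on = protocol.step_onset
    off = on + protocol.step_duration
    dv_ss = amplitude / params.leak_conductance

    def component(tau_c: float) -> np.ndarray:
        out = np.zeros_like(t)
        during = (t >= on) & (t < off)
        after = t >= off
        out[during] = dv_ss * (1.0 - np.exp(-(t[during] - on) / tau_c))
        v_off = dv_ss * (1.0 - np.exp(-protocol.step_duration / tau_c))
        out[after] = v_off * np.exp(-(t[after] - off) / tau_c)
        return out

    slow = component(tau)
    if params.fast_fraction > 0 and params.tau_fast_ms > 0:
        fast = component(params.tau_fast_ms)
        return el + (1.0 - params.fast_fraction) * slow + params.fast_fraction * fast
    return el + slow


def _simulate_sweep(
    params: NeuronModelParams,
    protocol: ProtocolSpec,
    amplitude: float,
    rng: np.random.Generator | None,
    noise_sd: float,
) -> Sweep:
    khz = protocol.sampling_rate
    dt = 1.0 / khz
    n = int(round(protocol.sweep_duration * khz)) + 1
    t = np.arange(n) * dt

    max_drive = max(amplitude, 0.0) if protocol.protocol_kind != "ramp" else max(amplitude, 0.0)
    v_inf_max = (
        params.resting_potential
        + (max_drive + params.tonic_current) / params.leak_conductance
    )
    if (
        protocol.protocol_kind in ("step_family", "rheobase_fine", "brief_pulse")
        and v_inf_max < params.spike_initiation_threshold
    ):
        v = _analytic_subthreshold(params, protocol, amplitude, t)
    else:
        v = _integrate_with_spikes(params, protocol, amplitude, t, dt)

    if noise_sd > 0:
        if rng is None:
            raise ValueError("noise requested without a random generator")
        v = v + rng.normal(0.0, noise_sd, size=n)
    kind = "ramp" if protocol.protocol_kind == "ramp" else "step"
    stim = Stimulus(amplitude, protocol.step_onset, protocol.step_duration, kind)
    return Sweep(time_ms=t, values=v, units="mV", sampling_khz=khz, stimulus=stim)


def _integrate_with_spikes(
    params: NeuronModelParams,
    protocol: ProtocolSpec,
    amplitude: float,
    t: np.ndarray,
    dt: float,
) -> np.ndarray:
    """Fixed-step exact-exponential integration with spliced spike waveforms."""
    n = t.size
    n_sub = max(1, math.ceil(dt / MAX_INTEGRATION_STEP_MS))
    h = dt / n_sub
    el = params.resting_potential
    gl = params.leak_conductance
    vt = params.spike_initiation_threshold
    tau_m = params.tau_m
    em = math.exp(-h / tau_m)
    ew = math.exp(-h / params.adaptation_time_constant)
    stim = _stimulus_current(protocol, amplitude, t)

    wf = _render_spike_waveform(params, dt)
    wf_len = wf.size
    wf_decay = math.exp(-((wf_len - 1) * dt) / params.adaptation_time_constant)

    out = np.empty(n)
    v = el + params.tonic_current / gl
    out[0] = v
    w = 0.0
    next_allowed = -math.inf
    i = 1
    while i < n:
        i_stim = stim[i - 1]
        for _ in range(n_sub):
            v_inf = el + (i_stim + params.tonic_current - w) / gl
            v = v_inf + (v - v_inf) * em
            w *= ew
        if not math.isfinite(v):
            raise FloatingPointError(
                f"integration diverged at step amplitude {amplitude} pA"
            )
        if v >= vt and t[i] >= next_allowed:
            stop = min(i + wf_len, n)
            out[i:stop] = wf[: stop - i]
            w = (w + params.adaptation_increment) * wf_decay
            v = params.reset_potential
            next_allowed = t[i] + params.refractory_period
            i = i + wf_len
        else:
            out[i] = v
            i += 1
    return out


def simulate_current_clamp(
    params: NeuronModelParams,
    protocol: ProtocolSpec,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[Sweep]:
    """One voltage sweep per protocol amplitude (additive Gaussian noise)."""
    if protocol.protocol_kind not in ("step_family", "rheobase_fine", "brief_pulse", "ramp"):
        raise ValueError(
            f"protocol kind {protocol.protocol_kind!r} is not a current-clamp protocol"
        )
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    sweeps = []
    for k, amp in enumerate(protocol.step_amplitudes):
        rng = np.random.default_rng([seed, k]) if noise_sd > 0 else None
        sweeps.append(_simulate_sweep(params, protocol, amp, rng, noise_sd))
    return sweeps


# ---------------------------------------------------------------------------
# voltage clamp


def simulate_vclamp_step(
    rin_mohm: float,
    cm_pf: float,
    step_mv: float = 10.0,
    protocol: ProtocolSpec | None = None,
    seed: int = 0,
    noise_sd_pa: float = 0.0,
    access_mohm: float = 10.0,
) -> Sweep:
    """Voltage-clamp step response: capacitive transient onto Ohmic steady state.

    Steady-state current is 1000*step/rin (pA); the transient decays with
    tau = rin*cm from an initial peak set by the access resistance.
    """
    if rin_mohm <= 0:
        raise ValueError("input resistance must be positive")
    if step_mv == 0:
        raise ValueError("voltage step must be nonzero")
    protocol = protocol or default_protocols()["vclamp"]
    khz = protocol.sampling_rate
    n = int(round(protocol.sweep_duration * khz)) + 1
    t = np.arange(n) / khz
    on = protocol.step_onset
    off = on + protocol.step_duration
    tau = rin_mohm * cm_pf * 1e-3  # MOhm * pF = us; /1000 -> ms
    i_ss = 1000.0 * step_mv / rin_mohm          # pA
    i_peak = 1000.0 * step_mv / access_mohm     # pA

    i = np.zeros(n)
    during = (t >= on) & (t < off)
    after = t >= off
    i[during] = i_ss + (i_peak - i_ss) * np.exp(-(t[during] - on) / tau)
    i_off = i_ss + (i_peak - i_ss) * math.exp(-protocol.step_duration / tau)
    i[after] = (i_off - i_peak) * np.exp(-(t[after] - off) / tau)
    if noise_sd_pa > 0:
        i = i + np.random.default_rng([seed, 0]).normal(0.0, noise_sd_pa, n)
    stim = Stimulus(step_mv, on, protocol.step_duration, "vstep")
    return Sweep(time_ms=t, values=i, units="pA", sampling_khz=khz, stimulus=stim)


# ---------------------------------------------------------------------------
# EPSC series


def _epsc_template(
    sweep_ms: float, khz: float, stim_ms: float, tau_rise: float, tau_decay: float
) -> np.ndarray:
    """Unit-peak double-exponential synaptic waveform on the sample grid."""
    n = int(round(sweep_ms * khz)) + 1
    t = np.arange(n) / khz
    dt = np.clip(t - stim_ms, 0.0, None)
    shape = np.where(
        t >= stim_ms, np.exp(-dt / tau_decay) - np.exp(-dt / tau_rise), 0.0
    )
    m = shape.max()
    return shape / m if m > 0 else shape


def generate_epsc_series(
    base_amplitude: float,
    effects: PlantedEffects = NULL_EFFECTS,
    stim_interval_s: float = 10.0,
    baseline_duration_s: float = 600.0,
    drug_duration_s: float = 900.0,
    noise_cv: float = 0.1,
    seed: int = 0,
    *,
    potentiation_factor: float | None = None,
    render_sweeps: bool = True,
    sampling_khz: float = 10.0,
    sweep_ms: float = 200.0,
    stim_time_ms: float = 10.0,
    tau_rise_ms: float = 3.0,
    tau_decay_ms: float = 40.0,
    current_noise_sd_pa: float = 0.0,
    rs_start_mohm: float = 12.0,
    rs_drift_sd_mohm: float = 0.05,
) -> EPSCSeries:
    """Timestamped evoked-EPSC sweeps over a baseline + drug time course.

    Event peak amplitude has mean ``base_amplitude`` during baseline and mean
    ``base_amplitude * factor`` after drug onset, with mean-preserving
    log-normal multiplicative noise of coefficient of variation ``noise_cv``.
    Events are rendered as inward (negative) deflections; all amplitudes are
    positive magnitudes.  A per-sweep series-resistance value (slow random
    walk) is emitted for QC testing.  ``render_sweeps=False`` skips waveform
    rendering and carries only the planted peak amplitudes (fast Monte-Carlo).
    """
    if base_amplitude < 0:
        raise ValueError("base amplitude is a magnitude and must be non-negative")
    if baseline_duration_s <= 0 or drug_duration_s <= 0:
        raise ValueError("baseline and drug durations must be positive")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    factor = (
        potentiation_factor
        if potentiation_factor is not None
        else effects.epsc_potentiation_factor
    )
    if factor <= 0:
        raise ValueError("potentiation factor must be positive")

    rng = np.random.default_rng([seed, 7])
    total = baseline_duration_s + drug_duration_s
    times = np.arange(stim_interval_s, total + 1e-9, stim_interval_s)
    means = np.where(times >= baseline_duration_s, base_amplitude * factor, base_amplitude)
    if noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + noise_cv**2))
        peaks = means * np.exp(rng.normal(-sigma**2 / 2.0, sigma, size=times.size))
    else:
        peaks = means.copy()
    rs = rs_start_mohm + np.cumsum(rng.normal(0.0, rs_drift_sd_mohm, size=times.size))

    template = (
        _epsc_template(sweep_ms, sampling_khz, stim_time_ms, tau_rise_ms, tau_decay_ms)
        if render_sweeps
        else None
    )
    events: list[EPSCEvent] = []
    n_samp = template.size if template is not None else 0
    t_axis = np.arange(n_samp) / sampling_khz if template is not None else None
    for k, (ts, peak, r) in enumerate(zip(times, peaks, rs)):
        sweep = None
        if template is not None:
            values = -peak * template
            if current_noise_sd_pa > 0:
                values = values + rng.normal(0.0, current_noise_sd_pa, n_samp)
            sweep = Sweep(
                time_ms=t_axis,
                values=values,
                units="pA",
                sampling_khz=sampling_khz,
                stimulus=Stimulus(0.0, stim_time_ms, 1.0, "synaptic"),
            )
        events.append(
            EPSCEvent(
                timestamp_s=float(ts),
                sweep=sweep,
                series_resistance_mohm=float(r),
                planted_amplitude_pa=float(peak),
            )
        )
    return EPSCSeries(
        events=events,
        drug_onset_s=baseline_duration_s,
        holding_potential_mv=-50.0,
        stim_time_ms=stim_time_ms,
    )


# ---------------------------------------------------------------------------
# paired cohorts


@dataclass
class CellTruth:
    """Ground truth for one synthetic cell (both conditions)."""

    cell_id: str
    baseline: NeuronModelParams
    drug: NeuronModelParams
    realized_delta_rmp: float
    realized_delta_threshold: float
    realized_delta_rheobase: float
    realized_epsc_factor: float
    epsc_base_amplitude: float
    rheobase_theory_baseline: float
    rheobase_theory_drug: float


@dataclass
class GroundTruthManifest:
    """Planted generator parameters for a paired baseline/drug cohort."""

    seed: int
    phenotype: str
    effects: PlantedEffects
    noise_sd_mv: float
    epsc_noise_cv: float
    cells: list[CellTruth]

    @property
    def mean_realized_delta_rmp(self) -> float:
        return float(np.mean([c.realized_delta_rmp for c in self.cells]))

    @property
    def mean_realized_delta_rheobase(self) -> float:
        return float(np.mean([c.realized_delta_rheobase for c in self.cells]))

    @property
    def mean_realized_delta_threshold(self) -> float:
        return float(np.mean([c.realized_delta_threshold for c in self.cells]))

    @property
    def mean_realized_percent_change(self) -> float:
        return float(np.mean([100.0 * (c.realized_epsc_factor - 1.0) for c in self.cells]))


@dataclass
class CellData:
    """In-memory recordings for one cell: sweeps per condition plus EPSC series."""

    cell_id: str
    sweeps: dict[str, dict[str, list[Sweep]]]  # condition -> protocol label -> sweeps
    epsc: EPSCSeries | None


def _realize_effects(effects: PlantedEffects, rng: np.random.Generator) -> tuple[float, float, float | None, float]:
    d_rmp = effects.delta_rmp + rng.normal(0.0, effects.sd_rmp) if effects.sd_rmp else effects.delta_rmp
    d_thr = (
        effects.delta_threshold + rng.normal(0.0, effects.sd_threshold)
        if effects.sd_threshold
        else effects.delta_threshold
    )
    d_rheo = effects.delta_rheobase
    if d_rheo is not None and effects.sd_rheobase:
        d_rheo = d_rheo + rng.normal(0.0, effects.sd_rheobase)
    factor = effects.epsc_potentiation_factor
    if effects.sd_epsc_factor:
        factor = max(factor + rng.normal(0.0, effects.sd_epsc_factor), 0.05)
    return d_rmp, d_thr, d_rheo, factor


def build_paired_cohort(
    n_cells: int,
    phenotype: str = "FS",
    effects: PlantedEffects = DEFAULT_FSIN_EFFECTS,
    protocols: dict[str, ProtocolSpec] | None = None,
    seed: int = 0,
    noise_sd: float = 0.3,
    epsc_base_amplitude: float = 120.0,
    epsc_noise_cv: float = 0.1,
    cell_rmp_jitter_sd: float = 1.0,
    render_epsc_sweeps: bool = True,
) -> tuple[list[CellData], GroundTruthManifest]:
    """Generate a baseline+drug cohort in memory with its ground-truth manifest.

    Seed scheme: per-cell effect realizations use generator streams seeded
    ``[seed, cell_index, 999]``; each sweep of each (condition, protocol)
    derives its stream from ``[seed, cell, condition, protocol, sweep]``
    indices, so any sweep is individually regenerable.
    """
    if n_cells < 2:
        raise ValueError("a paired cohort needs at least 2 cells")
    preset = fs_preset if phenotype == "FS" else pyr_preset
    cells: list[CellData] = []
    truths: list[CellTruth] = []
    for c in range(n_cells):
        rng = np.random.default_rng([seed, c, 999])
        el_jitter = rng.normal(0.0, cell_rmp_jitter_sd) if cell_rmp_jitter_sd else 0.0
        base = preset()
        base = replace(base, resting_potential=base.resting_potential + el_jitter)
        d_rmp, d_thr, d_rheo, factor = _realize_effects(effects, rng)
        drug = apply_effects(base, d_rmp, d_thr, d_rheo)
        protos = protocols if protocols is not None else default_protocols(
            fine_center_pa=theoretical_rheobase(base)
        )

        sweeps: dict[str, dict[str, list[Sweep]]] = {"baseline": {}, "drug": {}}
        for ci, (cond, p) in enumerate((("baseline", base), ("drug", drug))):
            for pi, (label, proto) in enumerate(sorted(protos.items())):
                if proto.protocol_kind == "vclamp_step":
                    sw = simulate_vclamp_step(
                        rin_mohm=p.input_resistance_mohm,
                        cm_pf=p.membrane_capacitance,
                        step_mv=proto.step_amplitudes[0],
                        protocol=proto,
                        seed=int(rng.integers(2**31)),
                        noise_sd_pa=2.0 if noise_sd > 0 else 0.0,
                    )
                    sweeps[cond][label] = [sw]
                elif proto.protocol_kind == "epsc_train":
                    continue
                else:
                    reps = 5 if proto.protocol_kind == "brief_pulse" and noise_sd > 0 else 1
                    out: list[Sweep] = []
                    for r in range(reps):
                        out.extend(
                            simulate_current_clamp(
                                p, proto, noise_sd=noise_sd,
                                seed=_sweep_seed(seed, c, ci, pi, r),
                            )
                        )
                    sweeps[cond][label] = out

        series = generate_epsc_series(
            base_amplitude=epsc_base_amplitude,
            effects=effects,
            noise_cv=epsc_noise_cv,
            seed=_sweep_seed(seed, c, 2, 0, 0),
            potentiation_factor=factor,
            render_sweeps=render_epsc_sweeps,
        )
        cells.append(CellData(cell_id=f"cell{c:02d}", sweeps=sweeps, epsc=series))
        truths.append(
            CellTruth(
                cell_id=f"cell{c:02d}",
                baseline=base,
                drug=drug,
                realized_delta_rmp=d_rmp,
                realized_delta_threshold=d_thr,
                realized_delta_rheobase=(
                    theoretical_rheobase(drug) - theoretical_rheobase(base)
                ),
                realized_epsc_factor=factor,
                epsc_base_amplitude=epsc_base_amplitude,
                rheobase_theory_baseline=theoretical_rheobase(base),
                rheobase_theory_drug=theoretical_rheobase(drug),
            )
        )
    manifest = GroundTruthManifest(
        seed=seed,
        phenotype=phenotype,
        effects=effects,
        noise_sd_mv=noise_sd,
        epsc_noise_cv=epsc_noise_cv,
        cells=truths,
    )
    return cells, manifest


def _sweep_seed(seed: int, cell: int, cond: int, proto: int, sweep: int) -> int:
    """Documented counter scheme: a distinct, reproducible stream per sweep."""
    ss = np.random.SeedSequence([seed, cell, cond, proto, sweep])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_paired_cohort(
    n_cells: int,
    out_dir,
    phenotype: str = "FS",
    effects: PlantedEffects = DEFAULT_FSIN_EFFECTS,
    protocols: dict[str, ProtocolSpec] | None = None,
    seed: int = 0,
    overwrite: bool = False,
    **kwargs,
):
    """Write a full baseline+drug dataset plus manifest.json to ``out_dir``.

    Returns (out_dir, GroundTruthManifest).  Refuses to write into an
    existing populated directory unless ``overwrite`` is set.
    """
    from . import dataset  # deferred: dataset imports types from this module

    cells, manifest = build_paired_cohort(
        n_cells, phenotype=phenotype, effects=effects, protocols=protocols,
        seed=seed, **kwargs,
    )
    path = dataset.write_cohort(out_dir, cells, manifest, overwrite=overwrite)
    return path, manifest
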