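"""Passive membrane properties: RMP, input resistance, membrane time constant.

Definitions used:

* **RMP** — mean voltage over the pre-stimulus window with +-2 ms around any
  detected spike masked out;
* **Rin (current clamp)** — OLS slope of steady-state voltage deflection
  against injected current over the -50..+20 pA / 10 pA family, spiking
  sweeps excluded;
* **Rin (voltage clamp)** — step voltage over baseline-subtracted
  steady-state current for a 10 mV step;
* **tau** — the *slow* component of a double-exponential fit of the voltage
  decay after a brief (-400 pA, 1 ms) hyperpolarizing pulse.

Steady state is measured over the last quarter of the step.  All fits expose
diagnostics; an r-squared below 0.9 raises a QC flag rather than failing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.optimize import curve_fit

from .trace_features import DetectionConfig, Sweep, SweepSet, detect_spikes

__all__ = [
    "PassiveProperties",
    "TauFit",
    "resting_potential",
    "input_resistance_cc",
    "input_resistance_vc",
    "membrane_tau",
    "average_sweeps",
]

STEADY_STATE_FRACTION = 0.25   # last quarter of the step
SPIKE_MASK_MS = 2.0
QC_R_SQUARED = 0.9


@dataclass
class TauFit:
    """Double-exponential fit diagnostics for the membrane time constant."""

    tau_slow: float
    tau_fast: float
    amp_slow: float
    amp_fast: float
    offset: float
    r_squared: float
    residual_norm: float
    ill_separated: bool = False
    qc_flags: list[str] = field(default_factory=list)


@dataclass
class PassiveProperties:
    rmp: float | None = None          # mV
    rin_cc: float | None = None       # MOhm
    rin_vc: float | None = None       # MOhm
    tau: float | None = None          # ms
    vi_r_squared: float | None = None
    tau_fit: TauFit | None = None
    qc_flags: list[str] = field(default_factory=list)


def resting_potential(
    sweep: Sweep, detection: DetectionConfig | None = None, margin_ms: float = 2.0
) -> float:
    """Mean pre-stimulus voltage, excluding +-2 ms around detected spikes.

    Requires at least 50 ms of pre-stimulus data; raises if spikes occupy the
    whole window.
    """
    if sweep.units != "mV":
        raise ValueError("RMP requires a voltage sweep")
    stop = sweep.index_at(sweep.stimulus.onset_ms - margin_ms)
    if stop * sweep.dt_ms < 50.0:
        raise ValueError("need at least 50 ms of pre-stimulus data for RMP")
    mask = np.ones(stop, dtype=bool)
    half = int(round(SPIKE_MASK_MS * sweep.sampling_khz))
    for p in detect_spikes(sweep, detection):
        if p - half < stop:
            mask[max(p - half, 0) : min(p + half + 1, stop)] = False
    if not mask.any():
        raise ValueError("spikes occupy the entire pre-stimulus window")
    return float(np.mean(sweep.values[:stop][mask]))


def _steady_state_deflection(sweep: Sweep) -> float:
    """Mean voltage over the last quarter of the step minus the pre-step mean."""
    i0, i1 = sweep.stimulus_window()
    tail = i1 - int(round((i1 - i0) * STEADY_STATE_FRACTION))
    pre_stop = sweep.index_at(sweep.stimulus.onset_ms - 1.0)
    return float(np.mean(sweep.values[tail:i1]) - np.mean(sweep.values[:pre_stop]))


def input_resistance_cc(
    sweeps: SweepSet, detection: DetectionConfig | None = None
) -> tuple[float, dict]:
    """Input resistance (MOhm) from the slope of the V-I plot.

    Steady-state deflection (last quarter of the step) is regressed on the
    injected current; sweeps containing spikes are excluded and reported in
    the diagnostics.  Needs >= 3 usable sweeps.
    """
    currents, deflections, excluded = [], [], []
    amps = [s.stimulus.amplitude for s in sweeps]
    if any(b <= a for a, b in zip(amps, amps[1:])):
        warnings.warn("V-I sweep amplitudes are not strictly increasing")
    for s in sweeps:
        if detect_spikes(s, detection):
            excluded.append(s.stimulus.amplitude)
            continue
        currents.append(s.stimulus.amplitude)
        deflections.append(_steady_state_deflection(s))
    if len(currents) < 3:
        raise ValueError(
            f"only {len(currents)} spike-free sweeps; need >= 3 for the V-I fit"
        )
    res = sps.linregress(currents, deflections)
    rin = 1000.0 * res.slope  # mV/pA = GOhm -> MOhm
    diag = {
        "r_squared": float(res.rvalue**2),
        "excluded_amplitudes": excluded,
        "n_used": len(currents),
        "implausible": bool(abs(rin) < 1.0),
    }
    if diag["implausible"]:
        warnings.warn("V-I slope is implausibly small (all deflections ~ 0)")
    return float(rin), diag


def input_resistance_vc(sweep: Sweep, step_mv: float | None = None) -> float:
    """Input resistance (MOhm) from the steady-state current of a voltage step."""
    if sweep.units != "pA":
        raise ValueError("voltage-clamp Rin requires a current sweep")
    step = step_mv if step_mv is not None else sweep.stimulus.amplitude
    if step == 0:
        raise ValueError("voltage step must be nonzero")
    i0, i1 = sweep.stimulus_window()
    tail = i1 - int(round((i1 - i0) * STEADY_STATE_FRACTION))
    pre_stop = sweep.index_at(sweep.stimulus.onset_ms - 1.0)
    delta_i = float(np.mean(sweep.values[tail:i1]) - np.mean(sweep.values[:pre_stop]))
    if abs(delta_i) < 1e-9:
        raise ValueError("steady-state current indistinguishable from baseline")
    return 1000.0 * step / delta_i  # mV/pA -> MOhm


def average_sweeps(sweeps: SweepSet) -> Sweep:
    """Pointwise average of repeated sweeps of the same protocol."""
    ref = sweeps[0]
    vals = np.mean([s.values for s in sweeps], axis=0)
    return Sweep(
        time_ms=ref.time_ms.copy(), values=vals, units=ref.units,
        sampling_khz=ref.sampling_khz, stimulus=ref.stimulus,
    )


def _double_exp(t, log_tau1, log_tau2, a1, a2, c):
    return a1 * np.exp(-t / np.exp(log_tau1)) + a2 * np.exp(-t / np.exp(log_tau2)) + c


def membrane_tau(sweep: Sweep, decay_duration_ms: float | None = None) -> TauFit:
    """Membrane time constant from the decay after a brief hyperpolarizing pulse.

    Fits V(t) = A1 exp(-t/tau1) + A2 exp(-t/tau2) + C to the post-pulse
    voltage decay (the caller averages repetitions first, see
    :func:`average_sweeps`) and returns the slower component with full
    diagnostics.  Initialization: tau guesses from log-linear fits to the
    early 10% and late 50% of the decay; amplitudes by linear least squares
    given those guesses.  Taus are kept positive by fitting in log space.
    """
    if sweep.units != "mV":
        raise ValueError("tau fit requires a voltage sweep")
    off = sweep.index_at(sweep.stimulus.onset_ms + sweep.stimulus.duration_ms)
    trough = off + int(np.argmin(sweep.values[off : off + int(5 * sweep.sampling_khz)]))
    stop = sweep.n_samples
    if decay_duration_ms is not None:
        stop = min(stop, trough + int(round(decay_duration_ms * sweep.sampling_khz)))
    t = sweep.time_ms[trough:stop] - sweep.time_ms[trough]
    v = sweep.values[trough:stop]
    if t.size < 20:
        raise ValueError("decay segment too short for a double-exponential fit")

    c0 = float(np.mean(v[-max(t.size // 20, 5) :]))
    d = v - c0
    sign = -1.0 if d[0] < 0 else 1.0
    mag = np.clip(sign * d, 1e-9, None)

    def _loglin(tt: np.ndarray, mm: np.ndarray, fallback: float) -> tuple[float, float]:
        """(tau, amplitude) from a log-linear fit of an exponential segment."""
        good = mm > 1e-6
        if good.sum() < 3:
            return fallback, float(sign * mm[0])
        slope, intercept = np.polyfit(tt[good], np.log(mm[good]), 1)
        if slope >= 0:
            return fallback, float(sign * mm[0])
        return float(-1.0 / slope), float(sign * np.exp(intercept))

    # peel-off initialization: slow component from the late half of the
    # decay, fast component from the early residual after subtracting it
    half = t.size // 2
    tau_slow0, a_slow0 = _loglin(t[half:], mag[half:], max(t[-1] / 5.0, 1e-3))
    resid = d - a_slow0 * np.exp(-t / tau_slow0)
    early = max(int(round(2.0 * sweep.sampling_khz)), 5)  # first ~2 ms
    rmag = np.clip(sign * resid[:early], 1e-9, None)
    tau_fast0, a_fast0 = _loglin(t[:early], rmag, tau_slow0 / 10.0)
    if tau_fast0 >= tau_slow0:
        tau_fast0 = tau_slow0 / 10.0
    basis = np.column_stack([np.exp(-t / tau_slow0), np.exp(-t / tau_fast0)])
    coef, *_ = np.linalg.lstsq(basis, d, rcond=None)
    a_slow0, a_fast0 = float(coef[0]), float(coef[1])

    # the tau_fast -> 0 corner is a spurious local minimum (an exponential
    # covering a single sample); multi-start over fast-tau guesses with
    # bounded log-taus keeps the optimizer out of it
    dt = 1.0 / sweep.sampling_khz
    lo = np.log(dt)
    hi = np.log(10.0 * t[-1])
    bounds = ([lo, lo, -np.inf, -np.inf, -np.inf],
              [hi, hi, np.inf, np.inf, np.inf])
    starts = {tau_fast0, tau_slow0 / 5.0, tau_slow0 / 20.0}
    popt, best_ss = None, np.inf
    last_err: RuntimeError | None = None
    for tf0 in sorted(starts):
        p0 = [np.clip(np.log(tau_slow0), lo + 1e-6, hi - 1e-6),
              np.clip(np.log(tf0), lo + 1e-6, hi - 1e-6), a_slow0, a_fast0, c0]
        try:
            cand, _ = curve_fit(_double_exp, t, v, p0=p0, bounds=bounds, maxfev=20000)
        except RuntimeError as err:
            last_err = err
            continue
        ss = float(np.sum((v - _double_exp(t, *cand)) ** 2))
        if ss < best_ss:
            popt, best_ss = cand, ss
    if popt is None:
        raise RuntimeError(
            f"double-exponential fit failed to converge (init taus "
            f"{tau_slow0:.3g}/{tau_fast0:.3g} ms): {last_err}"
        ) from last_err
    tau1, tau2 = float(np.exp(popt[0])), float(np.exp(popt[1]))
    a1, a2, c = float(popt[2]), float(popt[3]), float(popt[4])
    if tau1 >= tau2:
        tau_slow, a_slow, tau_fast, a_fast = tau1, a1, tau2, a2
    else:
        tau_slow, a_slow, tau_fast, a_fast = tau2, a2, tau1, a1

    resid = v - _double_exp(t, *popt)
    ss_tot = float(np.sum((v - np.mean(v)) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    fit = TauFit(
        tau_slow=tau_slow, tau_fast=tau_fast, amp_slow=a_slow, amp_fast=a_fast,
        offset=c, r_squared=r2, residual_norm=float(np.linalg.norm(resid)),
    )
    if tau_fast > 0 and abs(tau_slow - tau_fast) / tau_slow < 0.05:
        fit.ill_separated = True
        warnings.warn("double-exponential components are within 5% of each other")
    if r2 < QC_R_SQUARED:
        fit.qc_flags.append(f"tau fit r^2 = {r2:.3f} < {QC_R_SQUARED}")
        warnings.warn(fit.qc_flags[-1])
    return fit
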