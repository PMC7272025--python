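"""Firing-output analysis: F-I curves, sigmoid fits, rheobase, classification.

Firing frequency is the number of action potentials fired per second during
the depolarizing step.  The F-I relationship is fitted with a three-parameter
sigmoid

    f(I) = f_max / (1 + exp(-(I - x_half) / k))

whose reported "rising rate" is the slope of the linear mid-segment,
f_max / (4 k); the raw slope factor k is also returned so either convention
can be compared (an optional four-parameter variant adds a baseline offset).
Rheobase is the smallest step amplitude that elicits at least one spike, at
the resolution of the protocol grid.  Cells are classified as fast-spiking
when they sustain > 200 Hz at the top of the step range with near-unity
spike-frequency adaptation, and as pyramidal-like when adaptation is
pronounced.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .trace_features import DetectionConfig, Sweep, SweepSet, detect_spikes

__all__ = [
    "FICurve",
    "SigmoidFit",
    "RheobaseResult",
    "CellClassification",
    "ClassificationConfig",
    "build_fi_curve",
    "fit_fi_sigmoid",
    "rheobase",
    "select_rheobase_plus",
    "threshold_from_ramp",
    "classify_cell",
]

FS_RATE_CRITERION_HZ = 200.0


@dataclass
class FICurve:
    """Firing frequency (Hz) versus injected current (pA)."""

    currents: np.ndarray
    rates: np.ndarray
    step_duration_ms: float

    def __post_init__(self) -> None:
        self.currents = np.asarray(self.currents, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.currents.shape != self.rates.shape or self.currents.ndim != 1:
            raise ValueError("currents and rates must be 1-D arrays of equal length")
        if np.any(np.diff(self.currents) <= 0):
            raise ValueError("currents must be strictly increasing")
        if np.any(self.rates < 0):
            raise ValueError("rates must be non-negative")

    @property
    def max_rate(self) -> float:
        return float(np.max(self.rates)) if self.rates.size else 0.0

    @property
    def step_size(self) -> float:
        d = np.diff(self.currents)
        return float(np.min(d)) if d.size else 0.0


@dataclass(frozen=True)
class SigmoidFit:
    max_rate: float      # Hz
    xhalf: float         # pA
    k: float             # pA, sigmoid slope factor
    rising_rate: float   # Hz/pA, slope at xhalf = max_rate/(4k)
    offset: float        # Hz (0 for the 3-parameter form)
    r_squared: float
    extrapolated: bool   # xhalf outside the sampled current range +- one step


@dataclass(frozen=True)
class RheobaseResult:
    current_pa: float | None   # None when no sweep spiked
    resolution_pa: float       # protocol step size
    unbounded_below: bool = False

    @property
    def defined(self) -> bool:
        return self.current_pa is not None


@dataclass(frozen=True)
class ClassificationConfig:
    """FS/PYR decision boundaries.

    The >200 Hz sustained-rate requirement for FS cells is the standard
    physiological criterion; the adaptation-ratio cap and floor are
    configurable analysis choices, not literature constants.
    """

    fs_min_rate_hz: float = FS_RATE_CRITERION_HZ
    fs_max_adaptation: float = 1.3
    pyr_min_adaptation: float = 2.0


@dataclass(frozen=True)
class CellClassification:
    label: str                     # "FS" | "PYR" | "unclassified"
    max_sustained_rate: float
    adaptation_ratio: float
    evidence: str
    fluorescence_label: str | None = None
    conflict: bool = False


def build_fi_curve(
    sweeps: SweepSet, detection: DetectionConfig | None = None
) -> FICurve:
    """F-I curve from a family of depolarizing steps.

    Rate = spikes counted within the step window / step duration in seconds.
    All sweeps must share the step duration; amplitude gaps are allowed.
    """
    if not sweeps:
        raise ValueError("no sweeps supplied")
    durations = {s.stimulus.duration_ms for s in sweeps}
    if len(durations) != 1:
        raise ValueError(f"sweeps mix step durations: {sorted(durations)}")
    duration_ms = durations.pop()
    ordered = sorted(sweeps, key=lambda s: s.stimulus.amplitude)
    currents, rates = [], []
    for s in ordered:
        i0, i1 = s.stimulus_window()
        peaks = [p for p in detect_spikes(s, detection) if i0 <= p < i1]
        currents.append(s.stimulus.amplitude)
        rates.append(len(peaks) / (duration_ms / 1000.0))
    return FICurve(np.array(currents), np.array(rates), duration_ms)


def _sigmoid3(i, fmax, xhalf, k):
    return fmax / (1.0 + np.exp(-(i - xhalf) / k))


def _sigmoid4(i, fmax, xhalf, k, c):
    return c + fmax / (1.0 + np.exp(-(i - xhalf) / k))


def fit_fi_sigmoid(curve: FICurve, with_offset: bool = False) -> SigmoidFit:
    """Least-squares sigmoid fit of an F-I curve.

    Needs >= 4 points with >= 2 nonzero rates.  Initialization: f_max from
    the top rate, x_half from the current at half-maximal rate (interpolated),
    k from the span of the rising segment.
    """
    i, f = curve.currents, curve.rates
    if i.size < 4:
        raise ValueError("sigmoid fit needs at least 4 F-I points")
    if np.count_nonzero(f) < 2:
        raise ValueError("sigmoid fit refused: fewer than 2 nonzero rates")

    fmax0 = float(np.max(f))
    half = fmax0 / 2.0
    above = np.flatnonzero(f >= half)
    xhalf0 = float(i[above[0]]) if above.size else float(np.median(i))
    rising = np.flatnonzero((f > 0.05 * fmax0) & (f < 0.95 * fmax0))
    span = (i[rising[-1]] - i[rising[0]]) if rising.size >= 2 else (i[-1] - i[0]) / 4.0
    k0 = max(float(span) / 4.0, curve.step_size / 4.0, 1e-3)

    try:
        if with_offset:
            popt, _ = curve_fit(
                _sigmoid4, i, f, p0=[fmax0, xhalf0, k0, 0.0], maxfev=20000
            )
            fmax, xhalf, k, c = map(float, popt)
            pred = _sigmoid4(i, *popt)
        else:
            popt, _ = curve_fit(_sigmoid3, i, f, p0=[fmax0, xhalf0, k0], maxfev=20000)
            fmax, xhalf, k = map(float, popt)
            c = 0.0
            pred = _sigmoid3(i, *popt)
    except RuntimeError as err:
        raise RuntimeError(
            f"F-I sigmoid fit failed to converge (init fmax={fmax0:.3g} Hz, "
            f"xhalf={xhalf0:.3g} pA, k={k0:.3g} pA): {err}"
        ) from err

    ss_tot = float(np.sum((f - np.mean(f)) ** 2))
    r2 = 1.0 - float(np.sum((f - pred) ** 2)) / ss_tot if ss_tot > 0 else 1.0
    step = curve.step_size
    extrapolated = not (i[0] - step <= xhalf <= i[-1] + step)
    if extrapolated:
        warnings.warn(f"fitted xhalf {xhalf:.1f} pA lies outside the sampled range")
    return SigmoidFit(
        max_rate=fmax, xhalf=xhalf, k=k,
        rising_rate=fmax / (4.0 * k), offset=c, r_squared=r2,
        extrapolated=extrapolated,
    )


def rheobase(
    sweeps: SweepSet, detection: DetectionConfig | None = None
) -> RheobaseResult:
    """Minimum step amplitude that elicited spiking, at the grid resolution."""
    ordered = sorted(sweeps, key=lambda s: s.stimulus.amplitude)
    amps = [s.stimulus.amplitude for s in ordered]
    step = float(np.min(np.diff(amps))) if len(amps) > 1 else 0.0
    first_spiking = None
    for idx, s in enumerate(ordered):
        i0, i1 = s.stimulus_window()
        if any(i0 <= p < i1 for p in detect_spikes(s, detection)):
            first_spiking = idx
            break
    if first_spiking is None:
        warnings.warn("no sweep elicited spiking; rheobase undefined")
        return RheobaseResult(None, step)
    return RheobaseResult(
        float(amps[first_spiking]), step, unbounded_below=(first_spiking == 0)
    )


def select_rheobase_plus(
    sweeps: SweepSet, rheobase_pa: float, offset_pa: float = 50.0
) -> Sweep:
    """The sweep nearest rheobase + offset (ties broken upward).

    Single-AP waveform features are measured on this sweep.  Raises if no
    sweep lies within one grid step of the target.
    """
    if not sweeps:
        raise ValueError("no sweeps supplied")
    target = rheobase_pa + offset_pa
    amps = np.array([s.stimulus.amplitude for s in sweeps])
    dist = np.abs(amps - target)
    best = float(np.min(dist))
    candidates = np.flatnonzero(dist == best)
    pick = candidates[np.argmax(amps[candidates])]  # ties upward: more spikes
    step = float(np.min(np.diff(np.sort(amps)))) if amps.size > 1 else math.inf
    if best > step + 1e-9:
        raise ValueError(
            f"no sweep within one step ({step:g} pA) of rheobase+{offset_pa:g} "
            f"= {target:g} pA; nearest is {amps[pick]:g} pA"
        )
    if best > 1e-9:
        warnings.warn(
            f"no sweep exactly at {target:g} pA; using nearest ({amps[pick]:g} pA)"
        )
    return sweeps[int(pick)]


def threshold_from_ramp(
    ramp_sweep: Sweep,
    detection: DetectionConfig | None = None,
    feature_config=None,
) -> float | None:
    """AP threshold of the first spike elicited by a current ramp (mV).

    Returns None (with a warning) when the ramp elicited no spikes.
    """
    from .trace_features import FeatureConfig, ap_threshold

    peaks = detect_spikes(ramp_sweep, detection)
    if not peaks:
        warnings.warn("ramp elicited no spikes; ramp threshold undefined")
        return None
    cfg = feature_config or FeatureConfig()
    return ap_threshold(ramp_sweep, peaks[0], cfg).voltage


def classify_cell(
    curve: FICurve,
    adaptation_ratio: float,
    fluorescence_label: str | None = None,
    config: ClassificationConfig | None = None,
) -> CellClassification:
    """Functional FS/PYR classification from firing rate and adaptation.

    FS requires a maximal sustained rate above the FS criterion *and*
    adaptation below the cap; pronounced adaptation indicates PYR.
    Contradictory evidence (high rate with strong adaptation) yields
    "unclassified" with an explanatory note.  A fluorescence label, when
    given, is recorded and any disagreement flagged, never silently
    overridden.
    """
    config = config or ClassificationConfig()
    if curve.currents.size == 0:
        raise ValueError("cannot classify from an empty F-I curve")
    rate = curve.max_rate
    fast = rate > config.fs_min_rate_hz
    low_adapt = (not math.isnan(adaptation_ratio)) and adaptation_ratio < config.fs_max_adaptation
    high_adapt = (not math.isnan(adaptation_ratio)) and adaptation_ratio > config.pyr_min_adaptation

    if fast and low_adapt:
        label, evidence = "FS", (
            f"sustained {rate:.0f} Hz > {config.fs_min_rate_hz:.0f} Hz with "
            f"adaptation ratio {adaptation_ratio:.2f} < {config.fs_max_adaptation}"
        )
    elif fast and high_adapt:
        label, evidence = "unclassified", (
            f"conflict: rate {rate:.0f} Hz meets the FS criterion but "
            f"adaptation ratio {adaptation_ratio:.2f} is pronounced"
        )
    elif high_adapt:
        label, evidence = "PYR", (
            f"adaptation ratio {adaptation_ratio:.2f} > {config.pyr_min_adaptation}"
        )
    else:
        label, evidence = "unclassified", (
            f"rate {rate:.0f} Hz, adaptation ratio {adaptation_ratio:.2f} "
            "match neither phenotype"
        )
    conflict = False
    if fluorescence_label is not None and label in ("FS", "PYR"):
        conflict = fluorescence_label != label
        if conflict:
            evidence += (
                f"; fluorescence label {fluorescence_label!r} disagrees with "
                "the functional label"
            )
    return CellClassification(
        label=label, max_sustained_rate=rate, adaptation_ratio=adaptation_ratio,
        evidence=evidence, fluorescence_label=fluorescence_label, conflict=conflict,
    )
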