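"""Action-potential detection and single-AP waveform features.

Operates on current-clamp voltage sweeps.  The feature definitions follow
standard whole-cell practice for fast-spiking interneurons:

* **threshold** — voltage at which the third time-derivative of the
  (optionally Savitzky-Golay smoothed) voltage is maximal, searched in a
  short window before the spike peak;
* **amplitude** — threshold to peak;
* **half-width** — duration at the voltage halfway between threshold and
  peak, with sub-sample linear interpolation of the crossings;
* **fAHP** — threshold minus the post-spike voltage trough, reported as a
  positive magnitude when the trough lies below threshold;
* **max dV/dt** — maximal rate of rise between threshold and peak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "Stimulus",
    "Sweep",
    "SweepSet",
    "DetectionConfig",
    "FeatureConfig",
    "ThresholdResult",
    "APFeatures",
    "detect_spikes",
    "ap_threshold",
    "ap_amplitude_halfwidth",
    "ap_fahp",
    "max_dvdt",
    "adaptation_ratio",
    "extract_ap_features",
]


@dataclass(frozen=True)
class Stimulus:
    """Stimulus descriptor attached to a sweep.

    amplitude is in pA for current steps/ramps and mV for voltage steps;
    onset/duration in ms.  kind is free text (e.g. "step", "ramp", "vstep").
    """

    amplitude: float
    onset_ms: float
    duration_ms: float
    kind: str = "step"


@dataclass
class Sweep:
    """One uniformly sampled recorded trace plus its stimulus descriptor."""

    time_ms: np.ndarray
    values: np.ndarray
    units: Literal["mV", "pA"]
    sampling_khz: float
    stimulus: Stimulus

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.time_ms.ndim != 1 or self.time_ms.size < 2:
            raise ValueError("sweep needs at least 2 samples")
        if self.time_ms.shape != self.values.shape:
            raise ValueError("time and value arrays differ in length")
        if self.units not in ("mV", "pA"):
            raise ValueError(f"unsupported units {self.units!r}")
        dt = np.diff(self.time_ms)
        nominal = 1.0 / self.sampling_khz
        if np.any(np.abs(dt - nominal) > 0.01 * nominal):
            raise ValueError("sampling is not uniform at the stated rate")

    @property
    def dt_ms(self) -> float:
        return 1.0 / self.sampling_khz

    @property
    def n_samples(self) -> int:
        return self.time_ms.size

    def index_at(self, t_ms: float) -> int:
        """Index of the sample grid point nearest to time t_ms."""
        return int(round((t_ms - self.time_ms[0]) * self.sampling_khz))

    def stimulus_window(self) -> tuple[int, int]:
        """(start, stop) sample indices of the stimulus step, stop exclusive."""
        i0 = self.index_at(self.stimulus.onset_ms)
        i1 = self.index_at(self.stimulus.onset_ms + self.stimulus.duration_ms)
        return max(i0, 0), min(i1, self.n_samples)


SweepSet = Sequence[Sweep]


@dataclass(frozen=True)
class DetectionConfig:
    """Spike-detector settings.

    The default detector is a voltage crossing of ``level_mv`` with the peak
    taken as the local maximum between the upward and downward crossings;
    ``method="dvdt"`` instead triggers on the rate of rise exceeding
    ``dvdt_threshold`` (V/s).  Events closer than ``min_separation_ms`` to the
    previous accepted peak are discarded.
    """

    level_mv: float = 0.0
    min_separation_ms: float = 1.0
    method: Literal["crossing", "dvdt"] = "crossing"
    dvdt_threshold: float = 20.0


@dataclass(frozen=True)
class FeatureConfig:
    """Single-AP feature-measurement settings (all windows in ms)."""

    search_window_ms: float = 3.0      # pre-peak window for the threshold search
    smooth: bool = True
    smooth_window_ms: float = 0.5      # Savitzky-Golay window for derivatives
    smooth_polyorder: int = 4
    fahp_window_ms: float = 10.0       # post-peak cap for the trough search


@dataclass(frozen=True)
class ThresholdResult:
    voltage: float
    time_ms: float
    index: int


@dataclass(frozen=True)
class APFeatures:
    """Waveform measurements for one action potential."""

    threshold: float        # mV
    peak: float             # mV
    amplitude: float        # mV, threshold to peak
    half_width: float       # ms
    fahp: float             # mV, threshold - trough (positive magnitude)
    max_dvdt: float         # V/s
    threshold_time: float   # ms
    peak_time: float        # ms
    peak_index: int

    def __post_init__(self) -> None:
        if not self.peak > self.threshold:
            raise ValueError("AP peak must exceed threshold")
        if not self.half_width > 0:
            raise ValueError("half-width must be positive")
        if not self.threshold_time < self.peak_time:
            raise ValueError("threshold must precede peak")


def _require_voltage(sweep: Sweep) -> None:
    if sweep.units != "mV":
        raise ValueError("operation requires a voltage (mV) sweep")


def detect_spikes(sweep: Sweep, config: DetectionConfig | None = None) -> list[int]:
    """Return the sample indices of action-potential peaks in a voltage sweep."""
    config = config or DetectionConfig()
    _require_voltage(sweep)
    v = sweep.values
    if config.method == "crossing":
        above = v >= config.level_mv
    elif config.method == "dvdt":
        dvdt = np.gradient(v, sweep.dt_ms)  # mV/ms == V/s
        above = dvdt >= config.dvdt_threshold
    else:  # pragma: no cover - config is validated by construction
        raise ValueError(f"unknown detector method {config.method!r}")

    edges = np.flatnonzero(np.diff(above.astype(np.int8)) == 1) + 1
    if above[0]:
        edges = np.insert(edges, 0, 0)
    falls = np.flatnonzero(np.diff(above.astype(np.int8)) == -1) + 1

    min_sep = int(round(config.min_separation_ms * sweep.sampling_khz))
    peaks: list[int] = []
    for up in edges:
        later = falls[falls > up]
        down = later[0] if later.size else v.size
        seg = v[up:down]
        if seg.size == 0:
            continue
        peak = up + int(np.argmax(seg))
        if peaks and peak - peaks[-1] < min_sep:
            continue
        peaks.append(peak)
    return peaks


def _third_derivative(v: np.ndarray, dt: float, config: FeatureConfig) -> np.ndarray:
    """Third time-derivative of a voltage segment (mV/ms^3)."""
    if config.smooth:
        win = max(int(round(config.smooth_window_ms / dt)) | 1, config.smooth_polyorder + 2)
        if win % 2 == 0:
            win += 1
        if win <= v.size:
            return savgol_filter(v, win, config.smooth_polyorder, deriv=3, delta=dt)
    d3 = np.diff(v, n=3) / dt**3
    # align third differences with the sample at the start of the stencil
    return np.concatenate([d3, np.repeat(d3[-1] if d3.size else 0.0, 3)])


def ap_threshold(
    sweep: Sweep, peak_index: int, config: FeatureConfig | None = None
) -> ThresholdResult:
    """AP threshold: voltage where the third derivative of V(t) is maximal.

    The search runs from ``search_window_ms`` before the peak up to the peak;
    ties are broken toward the earliest sample.  Raises if the window is
    truncated by the sweep start.
    """
    config = config or FeatureConfig()
    _require_voltage(sweep)
    n_back = int(round(config.search_window_ms * sweep.sampling_khz))
    start = peak_index - n_back
    if start < 0:
        raise ValueError(
            f"threshold search window truncated by sweep start for spike at "
            f"index {peak_index} (needs {n_back} pre-peak samples)"
        )
    seg = sweep.values[start : peak_index + 1]
    d3 = _third_derivative(seg, sweep.dt_ms, config)
    idx = start + int(np.argmax(d3))  # argmax returns the earliest maximum
    return ThresholdResult(
        voltage=float(sweep.values[idx]),
        time_ms=float(sweep.time_ms[idx]),
        index=idx,
    )


def _interp_crossing(t0: float, t1: float, v0: float, v1: float, level: float) -> float:
    if v1 == v0:
        return t0
    return t0 + (level - v0) * (t1 - t0) / (v1 - v0)


def ap_amplitude_halfwidth(
    sweep: Sweep,
    peak_index: int,
    threshold: float,
    next_peak_index: int | None = None,
) -> tuple[float, float]:
    """Amplitude (threshold to peak, mV) and half-width (ms).

    The half-width is measured at threshold + amplitude/2 with linear
    interpolation between the bracketing samples.  Raises if the falling
    crossing is not found before the next spike (or sweep end).
    """
    _require_voltage(sweep)
    v = sweep.values
    t = sweep.time_ms
    peak_v = float(v[peak_index])
    amplitude = peak_v - threshold
    if amplitude <= 0:
        raise ValueError("degenerate AP: peak does not exceed threshold")
    half_level = threshold + amplitude / 2.0

    i = peak_index
    while i > 0 and v[i - 1] >= half_level:
        i -= 1
    if i == 0 and v[0] >= half_level:
        raise ValueError("rising half-amplitude crossing not found")
    t_rise = _interp_crossing(t[i - 1], t[i], v[i - 1], v[i], half_level)

    stop = next_peak_index if next_peak_index is not None else v.size
    j = peak_index
    while j + 1 < stop and v[j + 1] >= half_level:
        j += 1
    if j + 1 >= stop:
        raise ValueError("falling half-amplitude crossing not found before next spike")
    t_fall = _interp_crossing(t[j], t[j + 1], v[j], v[j + 1], half_level)

    return amplitude, float(t_fall - t_rise)


def ap_fahp(
    sweep: Sweep,
    peak_index: int,
    threshold: float,
    config: FeatureConfig | None = None,
    next_threshold_index: int | None = None,
) -> float:
    """Fast afterhyperpolarization: threshold minus the post-peak trough (mV).

    The trough is searched from the peak to ``fahp_window_ms`` later or to the
    next spike's threshold time, whichever comes first.  A non-positive value
    means the voltage never dipped below threshold (flagged by the caller).
    """
    config = config or FeatureConfig()
    _require_voltage(sweep)
    cap = peak_index + int(round(config.fahp_window_ms * sweep.sampling_khz))
    stop = min(cap, sweep.n_samples)
    if next_threshold_index is not None:
        stop = min(stop, next_threshold_index)
    if stop <= peak_index + 1:
        raise ValueError("empty post-peak window for fAHP")
    trough = float(np.min(sweep.values[peak_index + 1 : stop]))
    return threshold - trough


def max_dvdt(sweep: Sweep, peak_index: int, threshold_index: int) -> float:
    """Maximum rate of rise (V/s) between threshold and peak, central differences."""
    _require_voltage(sweep)
    if threshold_index >= peak_index:
        raise ValueError("threshold index must precede peak index")
    lo = max(threshold_index - 1, 0)
    hi = min(peak_index + 2, sweep.n_samples)
    dvdt = np.gradient(sweep.values[lo:hi], sweep.dt_ms)  # mV/ms == V/s
    a = threshold_index - lo
    b = a + (peak_index - threshold_index) + 1
    return float(np.max(dvdt[a:b]))


def adaptation_ratio(spike_times_ms: Sequence[float]) -> float:
    """Last inter-spike interval divided by the first.

    Requires at least 3 spikes; otherwise the ratio is undefined and NaN is
    returned with a warning.
    """
    times = np.asarray(spike_times_ms, dtype=float)
    if times.size < 3:
        warnings.warn("adaptation ratio undefined for fewer than 3 spikes")
        return float("nan")
    isis = np.diff(times)
    return float(isis[-1] / isis[0])


def extract_ap_features(
    sweep: Sweep,
    detection: DetectionConfig | None = None,
    config: FeatureConfig | None = None,
) -> list[APFeatures]:
    """Detect all spikes in a sweep and measure every single-AP feature.

    The number of returned records always equals the detector's spike count;
    a spike whose features cannot be measured raises rather than being
    silently dropped.
    """
    detection = detection or DetectionConfig()
    config = config or FeatureConfig()
    peaks = detect_spikes(sweep, detection)
    out: list[APFeatures] = []
    thresholds = [ap_threshold(sweep, p, config) for p in peaks]
    for k, (p, thr) in enumerate(zip(peaks, thresholds)):
        nxt_peak = peaks[k + 1] if k + 1 < len(peaks) else None
        nxt_thr = thresholds[k + 1].index if k + 1 < len(peaks) else None
        amp, hw = ap_amplitude_halfwidth(sweep, p, thr.voltage, nxt_peak)
        fahp = ap_fahp(sweep, p, thr.voltage, config, nxt_thr)
        dvdt = max_dvdt(sweep, p, thr.index)
        out.append(
            APFeatures(
                threshold=thr.voltage,
                peak=float(sweep.values[p]),
                amplitude=amp,
                half_width=hw,
                fahp=fahp,
                max_dvdt=dvdt,
                threshold_time=thr.time_ms,
                peak_time=float(sweep.time_ms[p]),
                peak_index=p,
            )
        )
    return out
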