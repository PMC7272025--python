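"""Evoked-EPSC amplitude time courses and drug-induced potentiation.

The experiment: NMDA-receptor-mediated EPSCs are evoked at a fixed interval
while the cell is voltage-clamped (here at -50 mV); after a 10-min baseline
the drug is washed in for 15 min.  Potentiation is quantified by comparing
the mean event amplitude in the final 5 min of drug to the 5 min immediately
preceding drug onset.  Recordings are terminated (not per-event filtered)
once series resistance exceeds a cap, mirroring standard whole-cell QC.

All amplitudes are positive magnitudes of inward (negative) currents.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .trace_features import Sweep

__all__ = [
    "EPSCEvent",
    "EPSCSeries",
    "PotentiationResult",
    "AmplitudeConfig",
    "measure_epsc_amplitude",
    "qc_series_resistance",
    "potentiation",
]

SERIES_RESISTANCE_CAP_MOHM = 25.0
BASELINE_WINDOW_S = 300.0
DRUG_WINDOW_S = 300.0


@dataclass
class EPSCEvent:
    """One evoked event: timestamp within the recording, the sweep, and QC data."""

    timestamp_s: float
    sweep: Sweep | None
    series_resistance_mohm: float
    planted_amplitude_pa: float | None = None  # ground truth, when synthetic


@dataclass
class EPSCSeries:
    """A continuous evoked-EPSC recording spanning baseline and drug."""

    events: list[EPSCEvent]
    drug_onset_s: float
    holding_potential_mv: float = -50.0
    stim_time_ms: float = 10.0
    truncated_at_s: float | None = None  # set by QC when the recording is cut

    def __post_init__(self) -> None:
        ts = [e.timestamp_s for e in self.events]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("event timestamps must be strictly increasing")
        if self.events and not (ts[0] <= self.drug_onset_s <= ts[-1]):
            warnings.warn("drug onset lies outside the recorded span")

    @property
    def span_s(self) -> float:
        return self.events[-1].timestamp_s if self.events else 0.0


@dataclass(frozen=True)
class AmplitudeConfig:
    """Peak-measurement settings (times relative to the stimulus, ms)."""

    search_start_ms: float = 2.0
    search_stop_ms: float = 50.0
    baseline_ms: float = 5.0         # pre-stimulus baseline window length
    baseline_gap_ms: float = 1.0     # baseline window ends this long before stimulus
    artifact_blank_ms: float = 1.0   # samples blanked either side of the stimulus


@dataclass(frozen=True)
class PotentiationResult:
    baseline_mean_pa: float
    drug_mean_pa: float
    percent_change: float
    n_baseline_events: int
    n_drug_events: int
    baseline_window_s: tuple[float, float]
    drug_window_s: tuple[float, float]
    qc_excluded: bool = False
    qc_reason: str = ""
    window_deviation: str = ""  # non-empty when QC truncation moved a window


def measure_epsc_amplitude(
    sweep: Sweep, stim_time_ms: float, config: AmplitudeConfig | None = None
) -> float:
    """Peak amplitude (pA, magnitude) of a single evoked EPSC sweep.

    The pre-stimulus baseline is the mean current over a window ending
    ``baseline_gap_ms`` before the stimulus; the event peak is the extremum of
    the baseline-subtracted current in a post-stimulus search window, with
    samples within ``artifact_blank_ms`` of the stimulus excluded.
    """
    config = config or AmplitudeConfig()
    if sweep.units != "pA":
        raise ValueError("EPSC measurement requires a current (pA) sweep")
    t0 = sweep.time_ms[0]
    if not (t0 <= stim_time_ms <= sweep.time_ms[-1]):
        raise ValueError("stimulus time lies outside the sweep")
    i_stim = sweep.index_at(stim_time_ms)

    b_stop = sweep.index_at(stim_time_ms - config.baseline_gap_ms)
    b_start = sweep.index_at(stim_time_ms - config.baseline_gap_ms - config.baseline_ms)
    b_start = max(b_start, 0)
    if b_stop <= b_start:
        raise ValueError("empty pre-stimulus baseline window")
    baseline = float(np.mean(sweep.values[b_start:b_stop]))

    s_start = sweep.index_at(stim_time_ms + config.search_start_ms)
    s_stop = sweep.index_at(stim_time_ms + config.search_stop_ms)
    blank_stop = sweep.index_at(stim_time_ms + config.artifact_blank_ms) + 1
    s_start = max(s_start, blank_stop, i_stim + 1)
    s_stop = min(s_stop, sweep.n_samples)
    if s_stop <= s_start:
        raise ValueError("empty post-stimulus search window")
    seg = sweep.values[s_start:s_stop] - baseline
    return float(np.max(np.abs(seg)))


def qc_series_resistance(
    series: EPSCSeries, cap_mohm: float = SERIES_RESISTANCE_CAP_MOHM
) -> EPSCSeries:
    """Truncate the series at the first event whose series resistance exceeds the cap.

    Termination semantics: everything from the offending event onward is
    dropped, matching the practice of ending the experiment rather than
    cherry-picking events.  Returns a new series; an empty result means the
    cell is excluded outright.
    """
    for k, ev in enumerate(series.events):
        if ev.series_resistance_mohm > cap_mohm:
            kept = series.events[:k]
            cut_at = ev.timestamp_s
            out = replace(series, events=kept, truncated_at_s=cut_at)
            return out
    return series


def _event_amplitude(ev: EPSCEvent, stim_time_ms: float, config: AmplitudeConfig) -> float:
    if ev.sweep is not None:
        return measure_epsc_amplitude(ev.sweep, stim_time_ms, config)
    if ev.planted_amplitude_pa is None:
        raise ValueError("event carries neither a sweep nor a planted amplitude")
    return ev.planted_amplitude_pa


def potentiation(
    series: EPSCSeries,
    baseline_window_s: float = BASELINE_WINDOW_S,
    drug_window_s: float = DRUG_WINDOW_S,
    amplitude_config: AmplitudeConfig | None = None,
) -> PotentiationResult:
    """Windowed baseline-vs-drug comparison of mean evoked amplitude.

    baseline window: the ``baseline_window_s`` seconds immediately before drug
    onset; drug window: the final ``drug_window_s`` seconds of the recording.
    When QC truncated the recording before its nominal end the drug window is
    measured backward from the last retained event and the deviation flagged.
    ``percent_change`` is 100*(drug - baseline)/baseline.
    """
    amplitude_config = amplitude_config or AmplitudeConfig()
    if not series.events:
        return PotentiationResult(
            float("nan"), float("nan"), float("nan"), 0, 0,
            (float("nan"), float("nan")), (float("nan"), float("nan")),
            qc_excluded=True, qc_reason="no events after QC",
        )

    onset = series.drug_onset_s
    b_lo, b_hi = onset - baseline_window_s, onset
    end = series.events[-1].timestamp_s
    d_lo, d_hi = end - drug_window_s, end
    deviation = ""
    if series.truncated_at_s is not None:
        deviation = (
            f"recording truncated by series-resistance QC at "
            f"{series.truncated_at_s:.0f} s; drug window measured backward "
            f"from last retained event"
        )
    if d_lo < onset:
        d_lo = onset
        deviation = (deviation + "; " if deviation else "") + (
            "drug window shortened to the retained post-onset span"
        )

    base_amps = [
        _event_amplitude(e, series.stim_time_ms, amplitude_config)
        for e in series.events
        if b_lo <= e.timestamp_s < b_hi
    ]
    drug_amps = [
        _event_amplitude(e, series.stim_time_ms, amplitude_config)
        for e in series.events
        if d_lo <= e.timestamp_s <= d_hi and e.timestamp_s >= onset
    ]
    if not base_amps or not drug_amps:
        return PotentiationResult(
            float("nan"), float("nan"), float("nan"),
            len(base_amps), len(drug_amps), (b_lo, b_hi), (d_lo, d_hi),
            qc_excluded=True, qc_reason="empty comparison window after QC",
            window_deviation=deviation,
        )
    base_mean = float(np.mean(base_amps))
    drug_mean = float(np.mean(drug_amps))
    return PotentiationResult(
        baseline_mean_pa=base_mean,
        drug_mean_pa=drug_mean,
        percent_change=100.0 * (drug_mean - base_mean) / base_mean,
        n_baseline_events=len(base_amps),
        n_drug_events=len(drug_amps),
        baseline_window_s=(b_lo, b_hi),
        drug_window_s=(d_lo, d_hi),
        window_deviation=deviation,
    )
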