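"""Shared fixtures: presets, protocols, and small reusable synthetic traces."""

import numpy as np
import pytest

from fsinephys import Stimulus, Sweep, fs_preset, pyr_preset
from fsinephys.synthetic_data import default_protocols, simulate_current_clamp


@pytest.fixture(scope="session")
def fs():
    return fs_preset()


@pytest.fixture(scope="session")
def pyr():
    return pyr_preset()


@pytest.fixture(scope="session")
def protocols():
    return default_protocols()


@pytest.fixture(scope="session")
def fs_fi_sweeps(fs, protocols):
    """Noiseless FS firing-output family (800 ms steps, 25-300 pA)."""
    return simulate_current_clamp(fs, protocols["fi"], noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def pyr_fi_sweeps(pyr, protocols):
    return simulate_current_clamp(pyr, protocols["fi"], noise_sd=0.0, seed=0)


def make_triangle_spike_sweep(
    spike_times_ms,
    baseline_mv=-70.0,
    peak_mv=20.0,
    base_width_ms=1.0,
    duration_ms=200.0,
    khz=20.0,
    onset_ms=10.0,
    step_pa=100.0,
):
    """Flat trace with symmetric triangular spikes at known times.

    The triangle rises from baseline to ``peak_mv`` over half the base width
    and falls back symmetrically; analytic geometry makes amplitude and
    half-width exact oracles.
    """
    n = int(round(duration_ms * khz)) + 1
    t = np.arange(n) / khz
    v = np.full(n, baseline_mv)
    half = base_width_ms / 2.0
    for ts in spike_times_ms:
        rise = (t >= ts - half) & (t < ts)
        fall = (t >= ts) & (t <= ts + half)
        v[rise] = baseline_mv + (peak_mv - baseline_mv) * (t[rise] - (ts - half)) / half
        v[fall] = baseline_mv + (peak_mv - baseline_mv) * ((ts + half) - t[fall]) / half
    stim = Stimulus(step_pa, onset_ms, duration_ms - 2 * onset_ms, "step")
    return Sweep(time_ms=t, values=v, units="mV", sampling_khz=khz, stimulus=stim)


@pytest.fixture
def triangle_sweep():
    return make_triangle_spike_sweep([50.0, 80.0, 120.0])
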