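# Methods

This note documents the models, estimators, numerical choices and
limitations behind `fsinephys`. Units are mV, pA, ms, nS, pF, MOhm and kHz
throughout; with these units dV/dt [mV/ms] = I [pA] / C [pF] and the
membrane time constant is tau = C/gL [ms].

## The synthetic neuron and why it looks the way it does

The generator's job is not biophysical realism but *verifiability*: every
quantity the pipeline estimates must have a planted, analytically known
value. The model is an adaptive leaky integrate-and-fire cell,

    C dV/dt = -gL (V - E_L) - w + I(t),      dw/dt = -w / tau_w,

with w incremented by b at each spike (spike-triggered adaptation only; no
subthreshold adaptation coupling). Integration uses the exact exponential
update for piecewise-constant input at the sampling interval, refined to
substeps of at most 0.05 ms when the protocol is sampled more coarsely.
Because the update is exact, subthreshold steady states obey Ohm's law to
machine precision and subthreshold decays are exact exponentials — the
passive-property oracles are therefore analytic, not numerical.

When V crosses the planted initiation voltage V_T, a stereotyped spike
waveform is spliced into the trace: a cubic-smoothstep rise from V_T to the
peak, then a smoothstep fall to the trough (= the reset potential), after
which integration resumes. The cubic smoothstep is C1 at onset with a jump
in the second derivative, so the third time-derivative of the rendered
trace is sharply maximal at the planted threshold sample — exactly the
property the third-derivative threshold estimator keys on. All five
waveform features have closed forms (`spike_waveform_truth`): amplitude
= peak - V_T, fAHP = V_T - reset, max dV/dt = 1.5 (peak - V_T)/t_rise,
half-width from the smoothstep crossings of V_T + amplitude/2.

Phenotype presets:

| parameter | FS | PYR | rationale |
|---|---|---|---|
| C (pF) / gL (nS) | 48 / 6 | 100 / 5 | tau_m 8 vs 20 ms |
| E_L (mV) | -70 | -72 | typical resting range |
| V_T (mV) | -45 | -42 | rheobase gL(V_T - E_L) = 150 pA, inside the 25-300 pA grid |
| reset (mV) | -58 | -55 | fAHP depth 13 mV |
| b (pA) / tau_w (ms) | 2 / 40 | 60 / 150 | near-unity vs pronounced adaptation |
| spike rise/fall (ms) | 0.4 / 0.4 | 0.5 / 0.9 | thin vs broad spikes |

The FS preset sustains ~220 Hz at 300 pA with adaptation ratio ~1.09
(< 1.3); the PYR preset adapts strongly (ratio > 2, often much higher).
The spike rise time is chosen so that the central-difference dV/dt
estimator stays within its stated 5% accuracy on the 20 kHz grids the
protocols use; a faster rendered upstroke would make the discrete maximum
slope intrinsically biased low at that sampling rate, which would test the
grid rather than the estimator.

A secondary fast charging component (fraction 0.1, tau 0.6 ms for FS)
emulates dendritic charge redistribution, giving brief-pulse responses a
genuine double-exponential decay whose slow component still equals C/gL.

### Planted drug effects

`PlantedEffects` carries the group-mean shifts and their between-cell SDs.
Rest and threshold shift the corresponding model parameters directly (the
reset tracks the threshold so fAHP depth is preserved). In a leaky
integrator the rheobase is identically gL (V_T - rest), so an *explicit*
planted rheobase shift cannot coexist with arbitrary voltage shifts at
fixed leak: when `delta_rheobase` is given, the drug-condition leak
conductance is solved to honor it exactly, and the implied small
input-resistance change (~3.5% for the default effects) is recorded in the
manifest. With `delta_rheobase=None` the rheobase shift follows from the
voltage shifts alone.

Shipped defaults for the FSIN group: ΔRMP +2.5 mV, Δthreshold -2.0 mV,
Δrheobase -25 pA, EPSC factor 1.83. Between-cell SDs (1.0 mV, 0.5 mV,
10 pA, 0.10) represent biological heterogeneity of the drug response —
roughly a third to a half of each effect size, so that an 8-cell cohort
detects the effect with realistic but not trivial power. Trace noise is
separate: additive Gaussian voltage noise (default 0.3 mV) on current-clamp
sweeps, and mean-preserving log-normal multiplicative noise on EPSC peak
amplitudes (`noise_cv`, default 0.1), chosen log-normal to keep amplitudes
positive.

### Protocols

Two step families deliberately coexist, bound to sweeps by metadata rather
than assumption: 500 ms steps from -100 to +300 pA in 50 pA increments
(characterization) and 800 ms steps from 25 to 300 pA in 25 pA increments
(firing output). Rheobase uses a dedicated 5 pA fine grid spanning -60/+40
pA around the cell's nominal rheobase; input resistance uses the -50..+20
pA / 10 pA family; tau the -400 pA / 1 ms pulse (5 repetitions averaged
when noise is on); voltage-clamp Rin a 10 mV step. The EPSC protocol
evokes events every 10 s (0.1 Hz — the stimulation frequency is a
generator choice) over a 10 min baseline + 15 min drug application, with a
hard amplitude transition at drug onset so the final-5-min window
comparison is exact by construction. Current-clamp sampling is 20 kHz;
10 kHz is the enforced minimum because third-derivative threshold
estimation degrades on sparser grids.

### Seeds

One master seed per cohort. Per-cell effect realizations draw from streams
seeded `[seed, cell, 999]`; each sweep's noise stream from
`[seed, cell, condition, protocol, sweep]` via `numpy` SeedSequence, so any
single sweep is regenerable in isolation and regeneration from (manifest,
seed) is byte-identical (fixed CSV float format, sorted JSON keys).

## Estimator details

**Threshold.** Savitzky-Golay smoothing-differentiation (window 0.5 ms,
polynomial order 4) computes the third derivative; raw third differences
amplify noise catastrophically and are used only when smoothing is
disabled. The search window is the 3 ms before the peak; ties break to the
earliest sample, which is deterministic and biased toward true initiation.
At 20 kHz the located sample can precede the splice by one sample, bounding
the estimator's systematic error at roughly the per-sample voltage advance
(< 0.25 mV under the default protocols); the zero-noise recovery test uses
0.25 mV as the documented threshold tolerance for this reason.

**Half-width** crossings are linearly interpolated between bracketing
samples, removing sampling-grid quantization. **fAHP** searches the trough
up to 10 ms after the peak or the next spike's threshold time, whichever is
earlier; a non-positive value (no trough below threshold) is returned
rather than raised, for the caller to flag. **max dV/dt** uses central
differences between threshold and peak.

**Spike detection** is a level crossing (default 0 mV) with the peak taken
as the local maximum before the downward crossing and a 1 ms minimum
separation; a dV/dt-trigger variant (default 20 V/s) is available in
config. Detection level sits far above synthetic noise floors, so detector
behavior under noise is benign by construction.

**Steady states** (V-I slope, voltage-clamp Rin) average the last 25% of
the step — late enough to settle several time constants under every
shipped protocol, long enough to average noise. Sweeps containing spikes
are excluded from the V-I fit and logged; fewer than 3 usable sweeps is an
error.

**Membrane tau.** The double-exponential fit parameterizes both time
constants in log space (positivity by construction) with bounds
[sample interval, 10x segment length]. Initialization is peel-off: the
slow component from a log-linear fit to the late half of the decay, the
fast component from the early residual after subtracting it, amplitudes by
linear least squares given the tau guesses. The tau_fast -> 0 corner is a
spurious local minimum (an exponential narrower than one sample can absorb
a single point), so the fit multi-starts over three fast-tau guesses and
keeps the lowest residual. Components within 5% of each other are flagged
ill-separated; fits with r^2 < 0.9 raise a QC flag and are never silently
accepted. The returned tau is always the slower component.

**F-I sigmoid.** Three parameters by default (a zero-baseline sigmoid; a
four-parameter variant with offset is available since the convention is
ambiguous in practice). "Rising rate" is reported as the mid-segment slope
f_max/(4k), with raw k alongside so either convention can be compared.
An x_half outside the sampled range (± one step) is flagged extrapolated.
Rheobase is the smallest spiking amplitude on the grid; its resolution is
the grid step and is always reported with it. The analysis sweep for
single-AP features is the one nearest rheobase + 50 pA, ties broken upward
(more spikes, more robust statistics).

**Classification.** FS requires sustained > 200 Hz *and* adaptation ratio
(last ISI / first ISI) below 1.3; pronounced adaptation (> 2.0) indicates
PYR. The rate criterion is the standard physiological definition; the
adaptation bounds are configurable analysis choices, surfaced in config
because no quantitative definition of "minimal adaptation" is established.
Contradictory evidence yields "unclassified" with a note; a fluorescence
label never silently overrides the functional label.

**EPSC amplitude** is the extremum of the baseline-subtracted current in a
2-50 ms post-stimulus window, artifact samples (±1 ms) blanked, baseline
from a 5 ms window ending 1 ms before the stimulus; amplitudes are positive
magnitudes of inward currents. An extremum statistic is biased high under
broadband trace noise, so the generator carries event-to-event variability
as amplitude noise (log-normal CV) and renders clean waveforms by default;
with real, noisy recordings a lowpass filter before measurement is
advisable and the bias should be kept in mind. Series-resistance QC uses
termination semantics — the series is truncated at the first event above
the 25 MOhm cap, never per-event filtered — and when truncation shortens
the recording the "final 5 min" drug window is measured backward from the
last retained event and the deviation flagged.

**Statistics.** "Paired comparisons" are two-tailed paired t tests
(df = n-1); the Wilcoxon signed-rank test uses the exact null distribution
for n ≤ 25 without rank ties (validated against full 2^n enumeration) and
the continuity-corrected normal approximation otherwise, dropping zero
differences per the standard convention with the count reported. The
repeated-measures ANOVA is the classical two-factor within-subject
decomposition; each within factor is tested against its own
factor-by-subject interaction, so the treatment effect has (1, n-1) df and
is immune to sphericity violations. The interaction p is reported both
uncorrected and Greenhouse-Geisser corrected (epsilon from the covariance
of orthonormal interaction contrasts) because the appropriate convention
is situation-dependent. No multiple-testing correction is applied by
default; `holm_adjust` exists for callers who want one.

## Pipeline

`run_pipeline` binds analyses to protocol labels in the dataset (CSV sweeps
with JSON sidecars; one directory per cell per condition, the EPSC series —
a single continuous recording spanning both conditions — under
`cell/epsc/`). Per-cell failures are isolated and logged without aborting
the cohort; every dropped sweep, spike, event or cell appears in the QC log
with a reason code. The effective config (hash), seed and package version
are archived with the outputs, and reruns with identical config and seed
produce byte-identical report tables. `recovery_check` compares each
recovered group effect against the manifest's realized per-cell values.

## What passing tests do and do not show

The generator's traces are clean by construction: noise is additive white
Gaussian (voltage) or log-normal (amplitudes), electrode artifacts, drift,
line noise and bridge-balance errors do not exist, and the planted spike
waveform is identical across spikes of a cell. Parameter recovery on these
data validates the estimators' correctness and their documented tolerances;
it does not certify performance on recordings with correlated noise,
unstable access resistance, or waveform variability. The sigmoid F-I model
is likewise an idealization — integrate-and-fire F-I curves are not exactly
sigmoid, which is visible in the fit diagnostics and is why fit r^2 is
always reported.

## Problem sizes

Test-suite and acceptance runs use cohorts of 2-8 cells with protocol
subsets matched to the quantity under test (e.g. the subthreshold family
for RMP recovery, the EPSC series alone for potentiation), 100-seed
Monte-Carlo loops for noise-robustness checks, and 2,000 simulated null
cohorts for type-I-error calibration — sizes at which every planted effect
is comfortably identifiable while the full suite runs in well under a
minute per module.
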