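# Methods

## Scope and data model

The package analyzes three kinds of intracellular data: current-clamp step
families (one `SweepSet` per cell), voltage-clamp current traces with
synaptic events, and simulated equivalents of both. Units are fixed
throughout: time in ms, voltage in mV, current in pA, resistance in MΩ,
charge in pC. Sample `i` of a trace occurs at `t0 + i·dt`; every module
reconstructs time this way and no other. The native on-disk dialect is a
two-column CSV per sweep plus a JSON sidecar per cell; it round-trips
bit-exactly and diffs cleanly. Binary acquisition formats (ABF, NWB) are an
optional adapter behind the same reader contract; without an adapter the
reader fails with a clear error rather than guessing.

## Intrinsic feature extraction

**Spike detection.** An upward crossing of dV/dt ≥ 20 mV/ms followed by the
next local voltage maximum, with a 1 ms merge window. The derivative is
taken on a 0.25 ms moving-average copy of the trace so recording noise of a
few hundred µV cannot forge upstrokes (raw derivative noise at σ = 0.2 mV
and dt = 0.05 ms is ~6 mV/ms — a third of the criterion); the peak index is
then refined on the raw samples. Detection counts are invariant to σ ≤
0.2 mV noise for spikes of ≥ 40 mV, which the tests check.

**AP threshold.** The voltage at which the third derivative of voltage with
time is maximal, searched from 3 ms before the spike peak to 0.25 ms before
it. The last quarter millisecond is excluded because at realistic sampling
the discrete third derivative is dominated by the sharp spike apex rather
than the take-off curvature. Two conditioning regimes, selected
deterministically by the measured noise level (1.4826·MAD of the first
difference):

- noise < 0.02 mV — cubic-spline interpolation evaluated at dt/20. On
  analytic waveforms this matches a dense finite-difference oracle to
  better than 0.1 mV. A polynomial smoothing filter is *not* applied here:
  at windows comparable to the upstroke time scale it biases the estimate
  1–5 mV up the rise.
- otherwise — Savitzky–Golay filtering (window ≈ 0.5 ms, order 3, third
  derivative), which tolerates recording noise at the cost of that bias;
  downstream features (amplitude, half-width, fAHP) shift by at most a few
  mV, which does not move cells across classification boundaries at
  realistic noise.

Ties break to the earliest time in both regimes.

**Other AP features.** Amplitude is threshold→peak; half-width is the trace
width at threshold + amplitude/2 with linear interpolation at both flanks;
max dV/dt is the steepest upstroke slope; fAHP is threshold minus the
voltage minimum between the peak and min(peak + 10 ms, the next spike's
take-off), reported as a non-negative magnitude. Features are measured on
the first AP of the sweep at rheobase + 50 pA (the nearest tested amplitude
above rheobase when that exact step was not tested; the sweep used is
recorded in the output).

**Train statistics.** SFA and the ISI coefficient of variation use the
lowest-amplitude sweep with ≥ 10 spikes (configurable); with fewer than
three spikes they are undefined, not zero. CV uses the sample (n−1)
standard deviation because event counts are small.

**Input resistance.** Least-squares slope of steady-state ΔV (mean over the
last 25 % of the step, relative to the pre-stimulus baseline) against
injected current, over spike-free sweeps only; mV/pA × 1000 → MΩ.

**Sag and rebound.** `sag_ratio = (V_ss − V_base)/(V_min − V_base)` — the
steady-state deflection as a fraction of the peak deflection on a
hyperpolarizing step (1 = no sag; an h-conductance gives < 1) — and rebound
as the post-stimulus peak minus baseline. This is the standard deflection
ratio; definitions vary in the literature and this one was chosen so a pure
RC response scores exactly 1.

## Classification

The fast-spiking rule is a conjunction of four strict inequalities:
half-width < 0.5 ms, maximum firing frequency > 50 Hz, fAHP > 14 mV,
SFA < 2. Boundary values classify regular-spiking. A cell with any feature
undefined (e.g. too few spikes for SFA) is *unclassifiable* — a third
outcome, because a missing feature must not masquerade as regular spiking.
Cutoffs are parameters of `FastSpikingClassifier` and are logged with every
result; the rule itself has nothing to fit, so `fit` only validates and
freezes them.

## Synaptic analysis

Events are outward (positive) currents, the convention for IPSCs recorded
at a +10 mV holding potential. The detector low-passes the trace (1 ms
moving average), takes a first difference — which turns each fast rising
phase into a sharp transient while suppressing slow decays, so events
riding on earlier tails are still seen — and thresholds at k = 4 times the
robust (MAD-based) noise scale of that conditioned signal, merging
detections closer than 5 ms. Genuinely overlapping events within the merge
window count once; this is the documented limitation of threshold
detection, and the generator-based tests measure recall (≥ 0.95 at 5 Hz,
SNR ≥ 5) rather than assuming perfection.

Amplitude is measured baseline-to-peak with the peak located on the
smoothed copy and read as a 1 ms mean around it — using the raw window
maximum would inflate amplitudes by ~3 noise SDs. The local baseline
averages the 2 ms before onset, excluding the onset sample. Decay τ is a
bounded single-exponential least-squares fit from the peak to the 10 %
level; a failed fit is reported (`decay_fit_ok = False`), never silently
defaulted. Charge integrates (trapezoid) from onset until the smoothed
trace first returns within 0.5 noise SD of baseline, capped at 200 ms.
Train analysis measures each pulse from its own local pre-pulse baseline,
so depression is not confounded by residual decay; PPR is the second
normalized amplitude.

## The conductance-based model

Single compartment: `C·dV/dt = i_inj/A − Σ_c ḡ_c·Π x^p·(V−E_c) −
g_L(V−E_L)`, gates `dx/dt = (x∞(V)−x)/τ_x(V)`. Channel kinetics live in a
data-driven registry of named functional forms (linoid, exponential,
sigmoid, bell, constant), serializable to YAML, so a configuration file can
swap kinetics without touching code. The default registry:

- `na_t`, `kdr_t` — Traub-type transient sodium and delayed rectifier with
  a −56.2 mV threshold shift; per-gate rate multipliers φ (0.7 on Na
  inactivation and Kdr activation in shipped models) slow the kinetics to
  an effective recording temperature, giving realistic regular-spiking
  half-widths (~0.8–1.2 ms).
- `km` — slow non-inactivating M-type potassium (σ(V; −35, 10), bell-shaped
  τ peaking at 200 ms), the source of spike-frequency accommodation.
- `kv31` — the fast high-threshold delayed rectifier: first-order
  activation, `m∞ = 1/(1+e^{−(V−18.7)/9.7})`,
  `τ = 4/(1+e^{−(V+46.56)/44.14})` ms (the public Allen Cell Types "Kv3_1"
  description). Its half-activation 40 mV above spike threshold and
  fast deactivation are what let it speed repolarization without loading
  the cell at rest.
- `hcn` — optional hyperpolarization-activated conductance for sag/rebound
  experiments.

**Somatic density scaling.** Published Kv3.1 densities for detailed
morphologies are *somatic* values; spread over the whole membrane of a
point model they overweight the channel several-fold (at 1.5 S/cm² the
subthreshold activation tail alone would clamp the cell). `NeuronModel`
therefore carries a per-channel `channel_scale` — the somatic area fraction
of the reduced geometry — so nominal densities stay on the published scale.
The four shipped models use fractions of 0.03–0.15, a per-cell geometry
property like membrane area.

**Shipped configurations.** `rs_a`…`rs_d` carry baseline nominal Kv3.1
densities of 0.25, 0.009, 0.29 and 0.56 S/cm² and differ in sodium/
potassium densities, leak, and area. All four are regular-spiking at
baseline; raising the nominal density to 1.5 S/cm² increases maximum firing
frequency, reduces SFA, narrows the AP and deepens the fAHP in every
configuration, and drives `rs_b` and `rs_c` across the classifier boundary
to fast-spiking. The fAHP margin shrinks as the baseline density grows
because the trough saturates near E_K (−90 mV); it does not grow strictly
monotonically along a fine density grid for the same reason, though the net
change from 0.1 to 1.5 S/cm² is strongly positive. The reduced model
reproduces the *direction* of all four effects, not the percent magnitudes
reported for morphologically detailed reconstructions, which remain an
external validation path.

**Integration.** Fixed-step, gates by the analytic exponential update
`x ← x∞ + (x−x∞)e^{−dt/τ}`, voltage by a semi-implicit step with
conductances frozen over dt — stable for stiff spiking systems. Default
dt = 0.025 ms for single-model experiments; cohort generation uses 0.05 ms
(convergence-tested: halving dt leaves spike counts unchanged and moves
spike times < 0.5 ms on the tested steps). The integrator is batched — a
whole stimulus family, or a chunk of cohort cells, advances in one
vectorized time loop — which is what keeps 200-cell cohorts at a few
minutes on one CPU. Runs settle 300 ms at zero current before recording;
a terminal |dV/dt| ≥ 0.01 mV/ms is reported in metadata. |V| > 200 mV
aborts with the offending batch member and time.

## Synthetic data

**Cohorts.** Each cell draws a base configuration, log-normal density/
passive jitter (sd 0.05 in log space), and a nominal Kv3.1 density from its
class range: regular-spiking 0.05–0.6 S/cm² (all four bases), fast-spiking
1.4–1.9 S/cm² (the `rs_b` template, whose near-zero baseline makes the
high-density phenotype robustly fast-spiking). Gaussian recording noise
(default σ = 0.2 mV) is added per sweep. Class parameters live in a YAML
profile (`configs/cohort_default.yaml`), not code. Determinism: cell `i`
draws from `SeedSequence(seed, spawn_key=(i,))`, so chunked and whole-cohort
generation agree bit-for-bit; diverging cells are redrawn with the attempt
count recorded. The classes overlap slightly near the half-width boundary
(~1 % of fast-class draws measure at 0.5 ms), which is intended — real
cohorts are not separable either.

**Synaptic recordings.** Poisson onsets, log-normal amplitudes (median
40 pA, log-sd 0.3), difference-of-exponentials waveforms
`A·(e^{−t/τ_d} − e^{−t/τ_r})` normalized to peak (defaults τ_r = 1.5 ms,
τ_d = 15 ms), rendered over 12 decay constants, plus Gaussian noise
(default σ = 3 pA). Default duration 60 s at 10 kHz — long enough for
~300 events at 5 Hz, which bounds recovery statistics, while keeping desk-
scale runtimes. Evoked trains scale a base amplitude by the
Tsodyks–Markram recursion (utilization `u`, resources `R`; facilitation
enabled by τ_fac > 0); with U = 0.5, τ_rec = 200 ms and a 100 ms interval
the closed-form PPR is 0.697, which the measurement pipeline reproduces
within 1 %.

What the generator does *not* emulate: correlated feature covariance
within a class (features are drawn independently), electrode/access
artifacts, baseline drift, temperature effects, and overlapping-event
statistics beyond Poisson timing. Passing recovery tests therefore shows
the pipeline is unbiased under these idealized conditions, not that it is
robust to every pathology of real recordings.

## Problem sizes and tolerances

The test suite and the acceptance script use: the 3⁴ boundary grid plus
10,000 random vectors for classifier equivalence; 1 s steps at 50–350 pA
(25 pA grid, dt = 0.025 ms) for the four-model Kv3.1 experiment; a
200-cell cohort (28 sweeps per cell, 800 ms steps, dt = 0.05 ms) for
mixture recovery with the binomial bound ±0.07 on a 0.3 weight; and a 60 s,
5 Hz recording (SNR ≈ 13) for synaptic recovery at 5 %. Feature oracles
assert 1 % on amplitude/R_in/charge, 2 % on half-width and decay τ, and
0.5 mV on threshold/fAHP.

## Known limitations

- The reduced model's fAHP values (40–50 mV from threshold) are larger
  than typical recorded values because a point model lacks the dendritic
  charge sink; directions, not magnitudes, are the validated quantity.
- The decay fit is single-exponential by design; genuinely biexponential
  decays will report an intermediate τ.
- The event detector merges events closer than 5 ms; at high rates
  measured frequency underestimates true rate by the resulting dead-time
  fraction (~2 % at 5 Hz).
- Thresholds from noisy traces carry the Savitzky–Golay bias described
  above (systematically a few mV depolarized).
- Liquid-junction-potential correction is out of scope; voltages are
  reported as recorded/simulated.
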