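# Methods

`sbcsim` models a low-frequency spherical bushy cell (SBC) of the rodent
anteroventral cochlear nucleus and the two cholinergic influences on it:
a fast-transient nicotinic (alpha7-type) synaptic conductance and a slow
muscarinic control of the resting membrane potential, represented as a
static shift of the leak reversal. The package simulates how both change
the cell's responses to auditory-nerve input: spike probability,
peristimulus time histograms, rate-level functions, frequency response
areas, and phase locking.

## Membrane model

Three compartments in a chain — soma, axon initial segment (AIS),
passive axon — coupled by fixed axial conductances. Conductances follow
the classic type-II ventral-cochlear-nucleus description:

| conductance | g_max | E_rev | location |
|---|---|---|---|
| leak | 14.5 nS total | −65 mV (control) | all, split by capacitance |
| Nav (m³h) | 1000 nS | +55 mV | AIS (all of it) |
| KLT (w⁴z) | 200 nS | −70 mV | soma |
| KHT (0.85 n²+0.15 p) | 175 nS | −70 mV | soma |
| Ih (r) | 40 nS | −43 mV | soma |

Gating uses Rothman–Manis-type rate equations at their 22 °C reference
values, with no temperature scaling. Total capacitance is 20.1 pF
(soma 12, AIS 3, axon 5.1).

### Calibration

The aggregate passive targets are a resting potential of −65.1 mV, an
input resistance at rest of 69.2 MΩ (= 1/14.45 nS, i.e. the leak
skeleton) and 20.1 pF. Compartment geometry, axial coupling and two
kinetic details are not constrained individually; the frozen calibration
is:

- **Axial conductances 500 and 150 nS**, leak split in proportion to
  capacitance. The passive (leak + axial) input resistance seen from the
  soma is then 69.70 MΩ and AIS spikes are read out at the soma with
  ≈ 90 mV amplitude.
- **Ih half-activation shifted to ≈ −87.5 mV** (a rigid −11.51 mV shift
  of the activation and time-constant curves relative to the guinea-pig
  reference), solved once so that the full model rests at exactly
  −65.1 mV with E_K at the canonical −70 mV. The hyperpolarized
  half-activation is in the range reported for rodent bushy-cell HCN
  channels. An alternative calibration through E_K alone (≈ −86 mV)
  also yields −65.1 mV but triples the standing KLT current, which
  makes the cell nearly insensitive to small tonic depolarizations —
  inconsistent with the measured cholinergic effect sizes. At the
  chosen operating point, the model reproduces them without further
  tuning: the 2 nS nicotinic event depolarizes the soma by 3.4 mV
  (measured: 3.7 ± 0.5 mV) and the ±10 mV leak-reversal shifts move the
  resting potential by +3.8/−4.6 mV.

`measure_passive` reports the resting potential of the **full** model
(zero-input equilibration) but the input resistance of the **passive
skeleton** (voltage-gated conductances removed, ΔV/ΔI for a −10 pA
probe). In a cell with this much subthreshold rectification the
steady-state voltage response to a current step measures KLT/Ih slope
conductance (~15–20 MΩ), not the passive membrane; the leak-skeleton
resistance is the quantity the printed parameterization pins down.

### Numerics

Fixed-step integration at dt = 10 µs: gate variables advance by
exponential Euler against the pre-step voltage; the voltages then take a
linearly implicit θ-step (Crank–Nicolson by default, backward Euler as
`solver_id="be"`) solved by the Thomas algorithm along the chain. The
scheme is unconditionally stable and, on a passive compartment, matches
the analytic RC step response to < 0.1 % of the step amplitude at
dt = 10 µs. Initial state is the exact resting fixed point (damped
Picard iteration on the resistive network with gates at steady state),
so zero-input traces are flat to numerical precision. Non-finite states
abort with the offending time step. Many sweeps are integrated as one
vectorized batch; identical inputs give bitwise-identical traces.

## Synapses

Conductance point sources on the soma, built by convolving unit-peak
difference-of-exponentials kernels (truncated at 10⁻⁴ of peak) with
input spike times:

- **Endbulb of Held**: one event per ANF spike, amplitudes i.i.d.
  Gaussian 55 ± 9 nS truncated at 0 (truncation mass ~10⁻⁹), reversal
  0 mV, kernel 0.1/0.2 ms (sub-millisecond AMPA-type).
- **Summed inhibition**: the same event times delayed 1 ms, fixed 24 nS
  per event, reversal −75 mV, kernel 0.5/3 ms. The slow-ish decay is
  deliberate: glycinergic/GABAergic inputs to SBCs are slow compared to
  the endbulb, and the sustained inhibitory conductance they build
  during driven activity is the background against which the
  cholinergic depolarization acts. A purely phasic kernel (≈ 2 ms
  decay) leaves only deep-refractory failures, which no 2–3 mV
  depolarization can rescue; decays ≥ 4 ms push driven rates below the
  spontaneous rate. `mode="off"` zeroes inhibition and scales the
  excitatory mean by 0.8 in compensation.
- **Nicotinic event**: one kernel per stimulus with time-to-peak 83 ms
  (τ_rise ≈ 27.7 ms solved from the peak-time relation), decay 461 ms,
  peak 2 nS, reversal 0 mV, starting 10 ms after tone onset. "Rise
  time" is interpreted as time-to-peak; both constants are
  configuration-exposed.
- **Muscarinic modulation**: a copy of the model with the leak reversal
  at −55 mV (`plus_ach`), −65 mV (`control`) or −75 mV (`minus_ach`),
  with no onset/offset dynamics — the fully developed effect.

## Synthetic auditory-nerve generator

A phenomenological high-spontaneous-rate fiber replaces a full inner-ear
model. Defaults: spontaneous 60 /s, saturated 250 /s, threshold
0 dB SPL, 20 dB dynamic range (smoothstep rate-level function),
primary-like onset adaptation (peak ratio 2.5, τ 10 ms), absolute dead
time 0.7 ms, CF-referenced triangular tuning (40 dB/oct above CF, a
shallow 10 dB/oct low-frequency tail below), and phase locking with
target vector strength 0.7 on the low-frequency plateau, rolling off as
a fourth-order low-pass with 2300 Hz corner (VS ≈ 0.6 at 1.7 kHz, ≈ 0.2
at 4 kHz, as in classic period-histogram data). Spikes are drawn by
thinning an inhomogeneous intensity — the rate profile times a unit-mean
von Mises factor whose concentration solves I₁(κ)/I₀(κ) = VS — with the
dead time enforced by rejection and a quasi-static hazard compensation
λ/(1−λr) so realized rates match the requested profile. Sweeps use
independent child streams of one seed; a seed fully determines a
stimulus set, so treatment conditions can be paired on identical
inputs.

The generator reproduces the *statistics* the bushy-cell model consumes,
not cochlear mechanics: no basilar-membrane filtering, two-tone
suppression, or long-range spontaneous correlations. Passing tests
therefore validate the neuron/synapse model under controlled input
statistics, not an end-to-end auditory periphery.

## Analysis definitions

- **Event classification**: APs are voltage peaks ≥ 40 mV above the
  trace median preceded (≤ 1 ms) by an upstroke ≥ 10 mV/ms, assigned to
  the nearest preceding input; EPSP = ≥ 1 mV depolarization above the
  pre-event baseline within a 4 ms window (capped at the next input);
  else complete failure. Thresholds cleanly separate the model's
  bimodal events and are configuration-exposed.
- **Spike probability** P_AP = #AP / (#AP + #EPSP); complete failures
  excluded.
- **Vector strength** |Σe^{iθ}|/n with θ = 2π·frac(t·f); preferred
  phase = circular mean; Rayleigh p = exp(−n·VS²) (large-n form),
  significant at p < 0.001.
- **Jitter**: sample (n−1) SD of AP latencies.
- **PSTH** 1 ms bins, rate-normalized; **RLF** over the tone window with
  the spontaneous rate from a 100 ms pre-stimulus window; **FRA**
  contours at spontaneous +5 and +50 spikes/s by marching squares.
- **Decay fits**: variable projection (amplitudes/baseline linear given
  the two time constants), log-spaced multi-start τ grid, Nelder–Mead
  polish in log-τ; r² = 1 − SS_res/SS_tot on the fitted segment;
  inclusion at r² > 0.8; τ_fast ≤ τ_slow by relabeling;
  τ_w = (A_f τ_f + A_s τ_s)/(A_f + A_s).

## Protocols and problem sizes

Tone protocols use 500 ms tones with 2 ms cos² ramps, a 100 ms
pre-stimulus window and 100 ms tail; the IVL protocol is 25 sweeps of
200 ms spontaneous + 200 ms driven (250 Hz, 40 dB SPL). The full
published grids (100 repetitions, 18 levels, 21 frequencies) are the CLI
defaults; the test suite runs the same protocols at 10–50 repetitions
and a rising-slope level subset, which already separates the paired
conditions well beyond their sampling noise.

## Known limitations

- Inhibition is static (fixed 24 nS/event); the activity-dependent
  plasticity of the real inputs is out of scope, so driven output rates
  are compressed (max ≈ 50–80 /s above threshold at CF) and the
  +50 spikes/s FRA contour of a strongly driven cell does not appear at
  the default operating point.
- The muscarinic effect is a pure reversal shift; no conductance change
  or kinetics, matching its "first-order" treatment.
- Somatic AP amplitudes and latencies depend on the frozen axial
  coupling; they were calibrated to the passive aggregate values, not
  to spike waveforms.
- Output jitter (~0.3 ms) is somewhat larger than the best in-vitro
  values, which mutes vector-strength effects above ~2 kHz.
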