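# sbcsim

Conductance-based simulation of a **spherical bushy cell (SBC)** — the
time-coding principal neuron of the anteroventral cochlear nucleus —
with **cholinergic modulation**, synthetic auditory-nerve input, and the
spike-timing statistics used to characterize such cells.

SBCs relay auditory-nerve spikes through the giant endbulb of Held
synapse with sub-millisecond precision. Besides this powerful bottom-up
drive they receive efferent cholinergic input, which acts on two time
scales: a weak, slow α7-nicotinic synaptic conductance (≈ 2 nS peak,
rise ≈ 83 ms, decay τ ≈ 461 ms, E_rev = 0 mV) and a muscarinic control
of the resting potential, modeled as a static shift of the leak reversal
(−55 mV "+ACh", −65 mV control, −75 mV "−ACh"). This package implements
the whole in-silico pipeline around those mechanisms:

- `sbcsim.model` — a three-compartment SBC (soma / Na-bearing axon
  initial segment / passive axon) with leak, Nav, low- and
  high-threshold K⁺ and Ih conductances (Rothman–Manis-type kinetics),
  integrated at 10 µs with a stable implicit scheme; passive
  characterization (`measure_passive`).
- `sbcsim.synapses` — EPSG/IPSG template kernels, spike-time → 
  conductance convolution, Gaussian endbulb amplitudes (55 ± 9 nS),
  delayed static inhibition (24 nS, E_rev −75 mV, 1 ms delay), the
  nicotinic event, and the muscarinic leak-reversal shift.
- `sbcsim.anf` — a synthetic high-spontaneous-rate auditory-nerve fiber:
  sigmoidal rate-level function, primary-like onset adaptation,
  refractoriness, von-Mises phase locking calibrated to vector strength
  0.7 at 250 Hz, and the "in-vivo-like" (IVL) protocol (25 sweeps of
  200 ms spontaneous + 200 ms driven at 250 Hz / 40 dB SPL).
- `sbcsim.analysis` — AP/EPSP/failure classification on voltage traces,
  spike probability P_AP = #AP/(#AP+#EPSP), PSTHs, rate-level
  functions, frequency response areas with iso-rate contours, vector
  strength with the Rayleigh criterion p = exp(−n·VS²) < 0.001, jitter.
- `sbcsim.fitting` — double-exponential decay fits with the weighted
  time constant τ_w = (A_f τ_f + A_s τ_s)/(A_f + A_s) and the r² > 0.8
  inclusion rule, peak conductance g = I/(V_hold − E_rev), and
  subthreshold I–V monitoring.
- `sbcsim.experiments` + a thin CLI — end-to-end protocols pairing
  treatment conditions on identical input spike sets.

See `docs/methods.md` for the model's assumptions, calibration and
limitations.

## Worked example

```bash
sbcsim run --protocol passive_check --out results/passive
```

prints

```json
{
  "rmp_mV": -65.09999996825871,
  "r_in_MOhm": 69.70374890404116,
  "c_total_pF": 20.1
}
```

the model's resting potential (mV), passive input resistance (MΩ) and
total capacitance (pF). From Python, a paired IVL experiment across the
three muscarinic conditions:

```python
from sbcsim import ProtocolConfig, run_protocol

bundle = run_protocol(ProtocolConfig(
    protocol="ivl", seed=1, n_reps=5, output_dir="results/ivl"))
for lab, s in bundle.summary["conditions"].items():
    print(lab, round(s["p_ap"], 3), round(s["vs"], 3))
```

```
minus_ach 0.219 0.712
control 0.26 0.726
plus_ach 0.291 0.685
```

Each row is one modulatory condition driven by the *same* input spike
trains: the spike probability P_AP rises from the hyperpolarized
(−75 mV) through the control to the depolarized (−55 mV) leak-reversal
condition, while the output vector strength at 250 Hz stays at the level
of the input locking (0.7) — increased excitability without loss of
temporal precision. Other protocols: `nicotinic` (paired PSTHs with and
without the nicotinic event at 3 kHz / 20 dB), `muscarinic` (rate-level
functions for the three reversals), `fra`, `phase_locking`; all write
`summary.json`, tidy CSV tables and a `manifest.json` with the full
configuration and seed.

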