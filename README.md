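# grcopt

Conductance-based models of the cerebellar granule cell (GrC) with
automatic tuning of their maximum ionic conductances by an
indicator-based evolutionary algorithm (IBEA), plus the analysis
machinery to decide whether a tuned model is a *granule cell* rather
than a curve fit: discharge-feature extraction, emergent-property
validation, and parameter-recovery experiments on synthetic ground
truth.

## The problem

In realistic neuron modelling the channel complement and kinetics are
constrained by experiment, but the maximum conductance densities
G<sub>i-max</sub> remain free and must be tuned until the model matches
recorded firing.  Because different G<sub>i-max</sub> combinations can
produce similar firing, a tuned model is only trustworthy if (i) the
optimizer can demonstrably recover known conductances from firing
features alone, and (ii) the tuned model reproduces behaviors that were
never used as objectives.  The GrC is the ideal test neuron: it is
electrotonically compact, its currents have been measured directly, and
it has rich emergent behaviors (inward rectification, theta-band
resonance, axonal conduction) to validate against.

## What is in the box

* `grcopt.channels` / `grcopt.kinetics` — Hodgkin–Huxley gates, a
  13-state Markov resurgent-Na scheme, a calcium shell with Nernst
  reversal, and the versioned `grc2026a` kinetics set.
* `grcopt.morphology` / `grcopt.engine` — mono- (sphere, r = 9.76 µm)
  and multi-compartment (4 dendrites + soma + AIS + 15-segment axon)
  GrC models; a population-vectorized fixed-step integrator
  (exponential-Euler gates, `expm` lookup for the Markov scheme,
  Crank–Nicolson voltages) with an adaptive LSODA reference path.
* `grcopt.features` — the ten discharge features (resting voltage, AP
  height/width/half-width, fast/slow AHP, first-spike delay, mean
  frequency, adaptation, ISI CV) and their z-scored objectives
  `z = |feature − mean| / sd` per stimulus amplitude (10, 16, 22 pA).
* `grcopt.ibea` — IBEA with the additive-ε indicator
  `I(a,b) = max_i (a_i − b_i)`, fitness
  `F(x) = Σ_{y≠x} −exp(−I(y,x)/(c·κ))`, environmental selection,
  binary tournaments, swap recombination and polynomial mutation;
  cycles with between-cycle range resets.
* `grcopt.validation` — f/I slope, rectification index, ZAP resonance,
  near-threshold oscillation spectra, conduction/back-propagation
  timing, input resistance, and conductance-deviation statistics.
* `grcopt.synth` — synthetic ground truth G\*, template generation, and
  parameter recovery (the accuracy benchmark of the whole pipeline).
* A thin `grcopt` CLI (`simulate`, `synth`, `optimize`, `validate`,
  `run`) over the library, and narrative scripts under `examples/`.

## Worked example

```bash
python examples/02_fi_curve_and_rin.py
```

prints, for the reference mono-compartment model (mid-range conductance
densities, grc2026a kinetics):

```
amplitude (pA)  frequency (Hz)  first-spike delay (ms)
          10            9.5              127.4
          16           58.3               37.7
          22           86.8               24.1

f/I slope: 6.44 spikes/s per pA (least squares over the spiking amplitudes)
input resistance: 1.47 GOhm (-10 mV voltage-clamp step from rest)
```

i.e. the hallmark GrC excitability: gigaohm input resistance, silence
below ~8 pA, and a steep, nearly linear f/I relation around
7 spikes·s⁻¹/pA whose first-spike delay collapses as the current grows.
`examples/01_simulate_step.py` prints the full feature set of one trace
(AP half-width ~0.5 ms, fast AHP near −63 mV, regular ~58 Hz discharge
at 16 pA); `examples/03_parameter_recovery.py` runs a small
ground-truth recovery and prints per-conductance percent errors;
`examples/04_emergent_properties.py` computes rectification, resonance
and axonal conduction.

## Documentation

`docs/methods.md` describes the model equations, the kinetics set and
its calibration, the numerical schemes, the optimization design, and
known limitations (including which published reference values the
shipped kinetics set does and does not reproduce).
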