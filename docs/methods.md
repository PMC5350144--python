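# Methods

## The model

A cerebellar granule cell (GrC) is simulated as a conductance-based
compartmental model.  Each compartment integrates the membrane equation

    Cm dV/dt = - sum_i [ g_i (V - E_i) ] + I_axial + I_inj

with Cm = 1 µF/cm², axial resistivity Ra = 100 Ω·cm, and ionic
conductances g_i = G_i-max × (open fraction).  Axial coupling between
adjacent compartments is the series resistance of the two half
cylinders, R = Σ 4·Ra·(L/2)/(π·d²).  Two reference morphologies ship
with the package:

* **mono** — a single sphere-equivalent soma (radius 9.76 µm, area
  ≈1197 µm²) carrying Na (transient), Nap (persistent), Nar
  (resurgent), KV, KA, Kslow (M-like), Kir, KCa, Ca-HVA and a leak;
* **multi** — four dendrites (15 × 0.75 µm), a cylindrical soma
  (5.8 × 5.6 µm), an axon initial segment (2.5 × 1.5 µm) and a 70 µm
  ascending axon (0.3 µm diameter) in 15 uniform segments.  Sodium
  channels live only on the AIS and axon and are represented by a
  unified 13-state Markov scheme (closed C1–C5, open O, open-blocked
  OB, inactivated I1–I6) whose open-blocked pathway carries the
  resurgent gating; Kir/Kslow/KA sit on the soma, KCa and Ca-HVA on the
  dendrites, leaks everywhere.  The dendritic leak reversal is −65 mV,
  the tonic-inhibition leak value of the GrC model family; the other
  sections use the ordinary −58 mV.  (An alternative configuration with
  a −16.5 mV dendritic leak reversal was evaluated and rejected: with
  the configured leak densities and somatic Kir interval it admits no
  resting state anywhere near the physiological range with a
  gigaohm-scale input resistance.)

HH-style channels use independent gating particles with
`m_inf(V)`/`tau(V)` (or α/β) curves; the calcium-activated KCa gate
uses Moczydlowski–Latorre rates driven by a first-order sub-membrane
calcium shell (depth 0.2 µm, resting 100 nM, decay rate "Calc" =
1.5 ms⁻¹; shell depth and decay configurable, the decay optionally an
optimization gene).  The calcium reversal potential is recomputed every
step from the Nernst relation with the instantaneous [Ca]i (z = 2);
with 2 mM external calcium and 100 nM at rest this gives the
129.3 mV reversal used for Ca-HVA.  Only the equilibrium potential is
updated; a full GHK flux formulation was considered and not adopted
because the only quantity the model consumes is the reversal itself.

Every gating rate is stored already normalized to 30 °C; the simulator
applies no Q10 scaling at run time, and the kinetics loader refuses a
set declared at any other temperature, so nothing can be double-scaled.

## The kinetics set (grc2026a)

The exact rate constants of the GrC channel family are configuration
data, shipped as a versioned YAML file with standard
sigmoid/bell/exponential/linoid parameterizations.  The parameters were
calibrated numerically, with every conductance density fixed at the
mid-range value of its experimental search interval, against the
canonical GrC phenotype: a silent, stable rest near −65 mV, gigaohm
input resistance, rheobase below 10 pA, a near-linear f/I relation of
roughly 7 spikes·s⁻¹/pA over 10–22 pA with first-spike delays that
shrink as the current grows, spike half-widths near 0.5 ms, a fast AHP
bottoming just above −65 mV, theta-band spike-rate resonance, and
Kir-mediated inward rectification.  The calibration was staged: the
subthreshold balance first (steady-state I–V analysis refined against
the simulated voltage-clamp protocol), then the spike machinery
(Na/KV/KCa/Ca-HVA) on single-spike traces, then the discharge
statistics and resonance with the slow currents.

Design choices in the set that deserve explanation:

* **Kir is steep and slow.**  Activation is centred at −82 mV with a
  4 mV slope and subthreshold time constants of hundreds of
  milliseconds.  Near rest Kir is nearly shut, so it contributes little
  to the voltage-clamp transient; under sustained hyperpolarizing
  current it activates regeneratively (its outward current above E_K
  accelerates the hyperpolarization) until the membrane parks just
  above E_K = −84.7 mV.  Successive −3/−6/−9 pA steps therefore crowd
  together near E_K — the classic inward-rectification signature, a
  rectification index well above 1 — while the small-signal behavior
  near rest stays gigaohm-scale.
* **The KA window straddles rest.**  Activation (v½ −52.5 mV) and
  inactivation (v½ −69 mV, steep) overlap around −65 mV, giving a
  resting window conductance; inactivation is fast above rest (few ms)
  and recovers slowly below it, so the A-current transient delays the
  first spike without re-arming at every afterhyperpolarization.
* **The resurgent current is an arming gate.**  The HH caricature of
  resurgent Na uses an opening gate `s` that activates during the spike
  and deactivates slowly (~10 ms) on repolarization — the post-spike
  reopening tail — and an availability gate `f` whose steady state
  *grows* with depolarization (v½ −42 mV, ceiling 0.68): stronger
  stimuli keep the open-channel-block pathway armed between spikes, so
  the post-spike inward tail, and with it the firing rate, grows
  supra-linearly with the injected current.  This is what gives the
  model its steep f/I relation while the near-rheobase discharge stays
  slow.
* **Kslow quenches bursts quickly but decays slowly.**  Its time
  constant is voltage-asymmetric (tens of ms when depolarized, ~100 ms
  near rest), which both caps the intra-burst rate under slow input
  modulation and produces the slow spike-frequency adaptation that
  keeps the near-rheobase rate low.  This shapes the ZAP response: the
  per-cycle output-frequency curve rises to an interior maximum in the
  theta band and falls off at higher chirp frequencies.

The 13-state Markov parameters follow the published resurgent-sodium
scheme family (activation ladder rates 150·e^{V/20} and 3·e^{−V/20}
ms⁻¹, opening/closing 150/40 ms⁻¹, block 1.75 ms⁻¹, unblock
0.03·e^{−V/25} ms⁻¹, closed-state inactivation 0.005 ms⁻¹ with
allosteric factor a = (Oon/Con)^{1/4}).

## Numerics

The default solver is a fixed-step scheme on a 0.025 ms grid, chosen so
optimization runs are bit-reproducible:

* gating particles advance by exponential Euler on tabulated
  `m_inf`/`tau` curves (exact for frozen voltage; 0.05 mV tables);
* Markov occupancies advance by a precomputed `expm(Q(V)·dt)` lookup
  (0.1 mV grid), unconditionally stable and occupancy-conserving to
  machine precision.  The explicit forward scheme with sub-stepping
  (`markov_step`) is kept as the reference integrator and the two agree
  to ~1e-5 per step; the lookup was adopted in the engine because
  spike-top rates (~10³ ms⁻¹) would otherwise force hundreds of
  substeps;
* voltages advance by a θ-method (Crank–Nicolson) solve of the
  compartment-coupled linear system, so stiff axial coupling and spike
  conductances never limit the step; voltage clamp uses backward Euler
  to keep the clamp transient monotone.

States initialize at their steady state for the configured resting
potential and settle at zero input before every protocol (0.1 ms steps
during settling).  Settling durations matter more than usual here: the
slow Kir equilibrates over seconds, so resting-state measurements
(voltage clamp, rectification) use multi-second pre-runs.  Halving the
step changes the first spike time of a 16 pA discharge by well under
0.05 ms and the mean rate by well under 1%; later spike times
accumulate a slow phase drift, as fixed-step schemes do, so convergence
is asserted on onset and rate rather than on late spike phases.  An
adaptive stiff solver (LSODA) over the same equations is available for
cross-checks.

The integrator is vectorized over a population axis: a whole IBEA
generation (individuals × stimulus amplitudes) advances in lock-step
through one numpy program, which is what makes desk-scale evolutionary
runs practical in pure Python.  Each batch row solves its own linear
system, so results are independent of batch composition.

Units: mV, ms, pA (stimuli), mS/cm² (densities), mA/cm² (reported
current densities), µF/cm², µm, mM, Ω·cm; conversions live in
`grcopt.constants`.

## Features and objectives

Ten features parameterize the discharge (resting voltage, AP
height/width/half-width, fast and slow AHP depth, time to first spike,
mean frequency, adaptation index, ISI CV), each evaluated at 10, 16 and
22 pA; every (feature, amplitude) pair is one objective, the z-scored
distance to the template mean.  Conventions fixed in the package:
detection threshold −20 mV with 1 ms refractoriness; the per-spike
threshold voltage is where dV/dt last rises through 20 mV/ms before the
peak (the baseline for width and half-width); the fast AHP is the
minimum within 5 ms of a peak, the slow AHP the minimum between spikes
with the first 5 ms excluded; mean frequency uses the last-spike
endpoint; ISI standard deviation uses the sample convention (ddof = 1);
missing features (too few spikes) score a fixed penalty of 250 per
objective so silent individuals always rank last.  Peak times are
refined by a parabolic fit through the three samples around the
maximum, which matters for conduction-delay measurements.

## Optimization

IBEA with the additive-ε indicator: objectives are normalized to [0, 1]
per selection, the pairwise indicator is scaled by its maximum absolute
value and κ = 0.05, fitness is the standard exponential sum,
environmental selection removes the worst individual and updates the
remaining fitness values until the population size is restored, and
mating is by binary tournament.  Variation: with probability 0.5 a
parent pair exchanges each gene with probability 0.25; with probability
0.5 a child is mutated, each gene perturbed by a bounded polynomial
step (η = 20) with probability 0.5.  Study-design parameters:
population 150 (mono) / 200 (multi), 50 generations per cycle, 10
cycles.  Between cycles the search range of every gene resets to the
envelope of the top decile of the final generation, expanded by 10 % of
its width and clipped to the initial ±50 % interval (the reset rule
itself is a package choice; only its existence is part of the study
design).  Ties break by stable population index, evaluations are cached
by gene vector, and identical seeds give bit-identical trajectories.
After the last cycle, only individuals that spiked at all three test
amplitudes count as valid granule cell models.

## Synthetic ground truth and parameter recovery

No experimental recordings are distributed, so the pipeline's accuracy
is assessed by parameter recovery: a ground-truth vector G\* is drawn
uniformly inside the search ranges (5 % margins, rejected until the
model fires ≥3 spikes at each amplitude so all ISI features exist),
noise-free templates are built from its simulated features with the
experimental standard deviations for normalization, and the optimizer
must re-find G\*.  Reported statistics are the per-gene percent errors
of the best valid individual and the valid-population mean.  Noise-free
templates are the default acceptance surface because they separate
algorithmic correctness from noise robustness; Gaussian template noise
at the experimental sds is available.  What synthetic recovery does not
emulate: electrode artifacts, raw voltage noise, and cell-to-cell
variability of the kinetics (only densities vary) — passing recovery
shows the estimator works when the model family is correct, not that
the family is correct for any particular cell.

Desk-scale budgets used by the shipped tests, chosen as the package's
own reduced designs: mono recovery with population 30, 15 generations ×
2 cycles, 2-s traces on a 0.05 ms grid; multi recovery with population
16, 6 generations × 1 cycle, 1.5-s traces.  The API runs the full study
budget unchanged.

## Validation protocols

* **f/I**: 6 pA steps from 10 to 34 pA (the headline slope uses the
  10/16/22 pA triplet with 5-s steps); least-squares slope over spiking
  amplitudes.
* **Inward rectification**: −3, −6, −9 pA steps of several seconds
  (the slow Kir needs time to engage); rectification index = chord
  conductance at −9 pA over −3 pA.  Passive models score exactly 1;
  the reference mono model scores well above 1 because its responses
  crowd toward E_K.
* **Resonance**: ZAP `A·sin(B·t²)` with A = 10 pA sweeping 0–10 Hz over
  30 s on a tonic offset of rheobase + 2 pA; instantaneous frequencies
  of adjacent spike pairs are averaged within each chirp cycle and
  plotted against the cycle's input frequency; the curve's peak is the
  resonance frequency (a mean-ISI-per-cycle reading is exposed as an
  option).
* **Near-threshold oscillations**: hold 1 pA below rheobase (bisection
  to ±0.5 pA) for 5 s; dominant frequency from the Hann-windowed,
  zero-padded spectrum of the mean-removed voltage above 1 Hz.
* **Conduction**: 16 pA somatic step; parabolic-refined peak times of a
  mid-train spike at two axonal sites of known separation give the
  conduction speed, and the |AIS − dendrite| peak-time difference the
  back-propagation delay.
* **Input resistance**: −10 mV, 100 ms somatic voltage-clamp step from
  a fully settled rest; Rin from the steady-state current change.

## Known limitations

The kinetics set is a calibrated reconstruction of the GrC channel
family's behavior, not a transcription of any published channel model.
The reference models reproduce the canonical discharge phenotype — the
f/I slope, the steep rate increase with current, shrinking first-spike
delays, spike shape, theta-band resonance, strong inward rectification,
and conductance recovery within the published per-gene tolerances — but
several printed reference values are *not* matched and are reported as
the model computes them:

* The mono input resistance measures ≈1.47 GΩ against the 1.3 GΩ
  reference: with the leak density fixed at its mid-range value
  (1.47 GΩ alone) the remaining subthreshold conductances nearly
  cancel (KA window and Kir against the persistent-Na amplification),
  and every calibration that pushed the transient to 1.30 GΩ either
  silenced the 10 pA response or destabilized the resting state.
* The multi model rests near −82 mV (just above E_K, held by the
  somatic Kir) rather than −76 mV, and its input resistance measures
  ≈0.6 GΩ against the 2.1 GΩ reference: a ~2 GΩ transient would
  require the somatic Kir to sit at a low-activation operating point
  that is dynamically unstable given the printed leak densities.
* Axonal conduction measures ≈0.4 mm/ms against 0.2 mm/ms, and
  AIS→dendrite back-propagation is effectively instantaneous
  (microseconds) against 0.2 ms: with the printed geometry and
  Ra = 100 Ω·cm the half-cylinder coupling makes the somatodendritic
  compartment electrically tight (the same tightness that keeps the
  soma-to-dendrite attenuation under 2 %), so peak times cannot lag by
  fractions of a millisecond; slowing the axonal sodium kinetics moves
  the speed the wrong way because propagation there is largely
  passive.
* Sub-threshold theta oscillations just below rheobase are strongly
  damped (sub-millivolt); the resonance protocol, not the oscillation
  spectrum, carries the theta-band evidence in this model.
* First-spike delays run longer than the canonical values at matched
  currents (the KA transient that buys the resting window conductance
  also delays onset); they still decrease monotonically with current.

No synaptic input, no stochastic gating, no temperature machinery, no
parallel-fiber extension of the axon.
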