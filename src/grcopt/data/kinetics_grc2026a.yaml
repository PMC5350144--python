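# grc2026a -- gating kinetics set for the cerebellar granule cell channel
# family.  All rates are normalized to 30 degC; the simulator applies no
# runtime Q10 scaling.  Functional forms: sigmoid a/(1+exp((v-v0)/k)),
# bell a/(exp((v-v0)/k)+exp(-(v-v0)/k2)), exp a*exp((v-v0)/k), linoid
# a*(v-v0)/(exp((v-v0)/k)-1), mlkca (Moczydlowski-Latorre, Ca-dependent).
# Parameters were calibrated (see docs/methods.md) so that the reference
# mono- and multi-compartment models at mid-range conductance densities
# reproduce the canonical granule cell phenotype: silent rest near -65 mV,
# input resistance near 1.3 GOhm, rheobase below 10 pA, a linear f/I
# relation of roughly 7 Hz/pA over 10-22 pA with delays shrinking as the
# current grows, and theta-band resonance and near-threshold oscillations.
name: grc2026a
temp_c: 30.0
channels:
  # transient sodium current (mono-compartment model)
  Na:
    type: hh
    gates:
      - name: m
        exponent: 3
        minf: {kind: sigmoid, a: 1.0, v0: -36.0, k: -4.5}
        tau: {kind: bell, a: 0.12, v0: -36.0, k: 14.0, k2: 14.0}
        tau_min: 0.02
      - name: h
        exponent: 1
        minf: {kind: sigmoid, a: 1.0, v0: -46.0, k: 5.0}
        tau: {kind: bell, a: 6.0, v0: -52.0, k: 12.0, k2: 12.0}
        tau_min: 0.15
  # persistent sodium current (near-threshold amplification)
  Nap:
    type: hh
    gates:
      - name: m
        exponent: 1
        minf: {kind: sigmoid, a: 1.0, v0: -47.0, k: -3.0}
        tau: {kind: bell, a: 8.0, v0: -50.0, k: 16.0, k2: 16.0}
        tau_min: 1.0
  # resurgent sodium current.  The HH caricature uses an opening gate s
  # that activates during the spike and deactivates slowly on
  # repolarization (the post-spike reopening tail), and an "arming" gate
  # f whose steady state grows with depolarization: stronger drive arms
  # more open-channel block, hence more resurgent current -- the
  # mechanism that sustains high-frequency firing at strong inputs.
  Nar:
    type: hh
    gates:
      - name: s
        exponent: 1
        minf: {kind: sigmoid, a: 1.0, v0: -20.0, k: -7.0}
        tau: {kind: bell, a: 10.0, v0: -55.0, k: 20.0, k2: 20.0}
        tau_min: 0.5
      - name: f
        exponent: 1
        minf: {kind: sigmoid, a: 0.68, v0: -42.0, k: -5.0}
        tau: {kind: bell, a: 18.0, v0: -55.0, k: 20.0, k2: 20.0}
        tau_min: 3.0
  # delayed-rectifier potassium current
  KV:
    type: hh
    gates:
      - name: n
        exponent: 4
        minf: {kind: sigmoid, a: 1.0, v0: -27.0, k: -9.0}
        tau: {kind: bell, a: 2.0, v0: -40.0, k: 25.0, k2: 25.0}
        tau_min: 0.25
  # A-type inactivating potassium current.  The activation/inactivation
  # window straddles the resting potential (first-spike delay and a
  # resistive window conductance at rest); inactivation is fast above
  # rest and recovers slowly below it.
  KA:
    type: hh
    gates:
      - name: a
        exponent: 3
        minf: {kind: sigmoid, a: 1.0, v0: -52.5, k: -7.0}
        tau: {kind: bell, a: 1.2, v0: -45.0, k: 20.0, k2: 20.0}
        tau_min: 0.3
      - name: b
        exponent: 1
        minf: {kind: sigmoid, a: 1.0, v0: -69.0, k: 4.0}
        tau: {kind: sigmoid, a: 60.0, v0: -66.0, k: 3.0}
        tau_min: 3.0
  # M-like slow potassium current (adaptation, oscillations, resonance)
  Kslow:
    type: hh
    gates:
      - name: n
        exponent: 1
        minf: {kind: sigmoid, a: 1.0, v0: -30.0, k: -6.5}
        tau: {kind: bell, a: 120.0, v0: -60.0, k: 7.0, k2: 30.0}
        tau_min: 8.0
  # inward-rectifier potassium current: steep activation just below rest
  # with slow kinetics in the subthreshold range, setting the resting
  # potential and the slow inward rectification under negative steps.
  Kir:
    type: hh
    gates:
      - name: d
        exponent: 1
        minf: {kind: sigmoid, a: 1.0, v0: -82.0, k: 4.0}
        tau: {kind: bell, a: 900.0, v0: -85.0, k: 20.0, k2: 20.0}
        tau_min: 20.0
  # calcium-dependent potassium current (fast AHP)
  KCa:
    type: hh
    gates:
      - name: c
        exponent: 1
        ca_dependent: true
        alpha: {kind: mlkca, a: 2.0, v0: 1.5e-3, k: 11.7, sign: 1}
        beta: {kind: mlkca, a: 1.5, v0: 1.5e-4, k: 11.7, sign: -1}
  # high-voltage-activated calcium current
  Ca-HVA:
    type: hh
    gates:
      - name: s
        exponent: 2
        minf: {kind: sigmoid, a: 1.0, v0: -18.0, k: -6.0}
        tau: {kind: bell, a: 0.6, v0: -20.0, k: 15.0, k2: 15.0}
        tau_min: 0.1
      - name: u
        exponent: 1
        minf: {kind: sigmoid, a: 1.0, v0: -40.0, k: 8.0}
        tau: {kind: bell, a: 30.0, v0: -40.0, k: 20.0, k2: 20.0}
        tau_min: 10.0
  # unified 13-state resurgent sodium scheme (multi-compartment model):
  # closed C1-C5, open O, open-blocked OB, inactivated I1-I6
  Na13:
    type: markov13
    params:
      alpha: 150.0
      alpha_vdep: 20.0
      beta: 3.0
      beta_vdep: -20.0
      gamma: 150.0
      delta: 40.0
      epsilon: 1.75
      zeta: 0.03
      zeta_vdep: -25.0
      con: 0.005
      coff: 0.5
      oon: 0.75
      ooff: 0.005
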