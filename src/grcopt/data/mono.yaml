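# Reference mono-compartment granule cell model: a single sphere-equivalent
# somatic compartment (radius 9.76 um) carrying the full channel complement.
# gmax_range is the experimentally constrained search interval (mean +/- 50%,
# mS/cm^2); the reference model uses the mid-range value of each interval.
# "Calc" (the calcium-pool decay rate, 1/ms) is an additional optimizable
# parameter.
mode: mono
kinetics: grc2026a
ra_ohm_cm: 100.0
v_init: -65.0
compartments:
  - label: soma
    shape: sphere
    radius_um: 9.76
    cm_uf_cm2: 1.0
channels:
  - {name: Na,     compartment: soma, gmax_range: [10.4, 15.6],       erev: 87.39}
  - {name: Nap,    compartment: soma, gmax_range: [1.60e-2, 2.40e-2], erev: 87.39}
  - {name: Nar,    compartment: soma, gmax_range: [0.4, 0.6],         erev: 87.39}
  - {name: KV,     compartment: soma, gmax_range: [2.4, 3.6],         erev: -84.69}
  - {name: KA,     compartment: soma, gmax_range: [3.2, 4.8],         erev: -84.69}
  - {name: Kslow,  compartment: soma, gmax_range: [0.28, 0.42],       erev: -84.69}
  - {name: Kir,    compartment: soma, gmax_range: [0.72, 1.1],        erev: -84.69}
  - {name: KCa,    compartment: soma, gmax_range: [3.2, 4.8],         erev: -84.69}
  - {name: Ca-HVA, compartment: soma, gmax_range: [0.37, 0.55],       erev: ca}
  - {name: Lkg1,   compartment: soma, gmax_range: [4.54e-2, 6.82e-2], erev: -58.0}
calcium:
  compartments: [soma]
  ca_rest_mM: 1.0e-4
  ca_out_mM: 2.0
  beta_ca: 1.5
  beta_ca_range: [0.75, 2.25]
  shell_depth_um: 0.2
  optimize_beta: true
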