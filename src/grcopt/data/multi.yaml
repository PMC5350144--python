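# Reference multi-compartment granule cell model: 4 dendrites, soma, axon
# initial segment (AIS) and a 70 um ascending axon split into 15 uniform
# segments.  Sodium channels (13-state Markov scheme) live only on AIS and
# axon; Kir/Kslow/KA on the soma; KCa/Ca-HVA on the dendrites; leak
# everywhere.  "dendrite"/"axon" compartment entries are templates expanded
# into dendrite_1..4 / axon_1..N; channels placed on a template are placed
# on every expanded section with the same density.
mode: multi
kinetics: grc2026a
ra_ohm_cm: 100.0
v_init: -82.0
axon_segments: 15
compartments:
  - label: dendrite
    shape: cylinder
    diam_um: 0.75
    length_um: 15.0
    count: 4
    cm_uf_cm2: 1.0
    attach: soma
  - label: soma
    shape: cylinder
    diam_um: 5.8
    length_um: 5.6
    cm_uf_cm2: 1.0
  - label: AIS
    shape: cylinder
    diam_um: 1.5
    length_um: 2.5
    cm_uf_cm2: 1.0
    attach: soma
  - label: axon
    shape: cylinder
    diam_um: 0.3
    length_um: 70.0
    cm_uf_cm2: 1.0
    attach: AIS
channels:
  - {name: Na13,   compartment: AIS,      gmax_range: [179.1, 388.6],         erev: 87.39}
  - {name: Na13,   compartment: axon,     gmax_range: [1.74, 2.9],            erev: 87.39}
  - {name: KV,     compartment: AIS,      gmax_range: [26.7, 44.5],           erev: -84.69}
  - {name: KV,     compartment: axon,     gmax_range: [3.3, 5.59],            erev: -84.69}
  - {name: KA,     compartment: soma,     gmax_range: [4.0, 10.0],            erev: -84.69}
  - {name: Kslow,  compartment: soma,     gmax_range: [0.18, 0.31],           erev: -84.69}
  - {name: Kir,    compartment: soma,     gmax_range: [1.91, 3.18],           erev: -84.69}
  - {name: KCa,    compartment: dendrite, gmax_range: [2.85, 4.76],           erev: -84.69}
  - {name: Ca-HVA, compartment: dendrite, gmax_range: [4.38, 14.3],           erev: ca}
  - {name: Lkg,    compartment: dendrite, gmax_range: [1.6908e-2, 2.4798e-2], erev: -65.0}
  - {name: Lkg,    compartment: soma,     gmax_range: [8.04e-2, 0.13],        erev: -58.0}
  - {name: Lkg,    compartment: AIS,      gmax_range: [7.214e-2, 0.25],       erev: -58.0}
  - {name: Lkg,    compartment: axon,     gmax_range: [6.4319e-3, 1.071e-2],  erev: -58.0}
calcium:
  compartments: [dendrite]
  ca_rest_mM: 1.0e-4
  ca_out_mM: 2.0
  beta_ca: 1.5
  beta_ca_range: [0.75, 2.25]
  shell_depth_um: 0.2
  optimize_beta: true
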