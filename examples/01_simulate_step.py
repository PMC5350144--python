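"""Simulate the reference mono-compartment granule cell at one current step.

Builds the shipped mono model (mid-range conductance densities, grc2026a
kinetics), injects a 16 pA step for 2 s, and prints the discharge
features.  The granule cell should rest near -65 mV, start firing after
a delay of a few tens of ms, and discharge regularly at some tens of Hz.
"""

from grcopt import build_model, detect_spikes, extract_features, simulate
from grcopt.protocols import step_protocol

model = build_model("mono")
protocol = step_protocol(16.0, duration_ms=2000.0, pre_ms=100.0)
trace = simulate(model, protocol)

spikes = detect_spikes(trace)
features = extract_features(trace, spikes, (100.0, 2100.0),
                            stimulus_pA=16.0)

print(f"spikes detected:      {spikes.n}")
for name, value in features.as_dict().items():
    print(f"{name:>20s}: {value:8.3f}")
print()
print("resting_voltage is the pre-stimulus mean (mV); mean_frequency is "
      "spikes per second over the discharge; AP_width/half_width are in "
      "ms, the AHP depths are absolute voltages (mV).")
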