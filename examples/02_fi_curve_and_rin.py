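"""Frequency/current relation and input resistance of the mono model.

The granule cell's hallmark excitability: a high input resistance near
1.3 GOhm and a steep, nearly linear f/I relation (about 7 spikes/s per
pA over 10-22 pA) with first-spike delays that shrink as the current
grows.
"""

from grcopt import build_model, fi_curve, input_resistance

model = build_model("mono")

fi = fi_curve(model, amplitudes=(10.0, 16.0, 22.0), duration_ms=2000.0)
print("amplitude (pA)  frequency (Hz)  first-spike delay (ms)")
for a, f, d in zip(fi.amplitudes_pA, fi.frequency_hz,
                   fi.first_spike_delay_ms):
    print(f"{a:12.0f} {f:14.1f} {d:18.1f}")
print(f"\nf/I slope: {fi.slope_hz_per_pA:.2f} spikes/s per pA "
      "(least squares over the spiking amplitudes)")

rin = input_resistance(model)
print(f"input resistance: {rin:.2f} GOhm "
      "(-10 mV voltage-clamp step from rest)")
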