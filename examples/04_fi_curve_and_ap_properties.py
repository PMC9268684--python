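"""Current-clamp analysis: F-I curve and first-AP properties.

Generates a sweep set with 100 pA steps from -70 mV (rheobase 150 pA,
0.3 Hz/pA), builds the frequency-current curve, and measures the first
action potential's threshold, amplitude, AHP, and half-amplitude width.
"""

from dgephys import ap_properties, fi_curve, generate_intracellular_sweeps
from dgephys.errors import NoAPError

sweeps = generate_intracellular_sweeps(seed=11)
fi = fi_curve(sweeps)
print("F-I curve (current pA -> frequency Hz):")
print(fi.to_string(index=False))

for sweep in sweeps:
    try:
        props = ap_properties(sweep)
    except NoAPError:
        continue
    print(f"\nfirst AP at {sweep.injected_current_pa:.0f} pA: "
          f"threshold {props.threshold_mv:.1f} mV, amplitude {props.amplitude_mv:.1f} mV, "
          f"AHP {props.ahp_mv:.1f} mV, half-width {props.half_width_ms:.2f} ms")
    break
# Frequency is zero below rheobase and rises linearly at 0.3 Hz/pA above it;
# AP properties are measured on the first spike a suprathreshold step evokes.
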