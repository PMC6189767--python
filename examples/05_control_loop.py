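"""Threshold feedback over repeated injection attempts.

Two partial boluses of -6 nA each: the first attempt leaves the
accumulated drop above the -11 nA threshold (retry), the second crosses
it (success) and the loop terminates.
"""

from cytoclamp import analysis, presets, protocol

preset = presets.load_circuit_preset("shsy5y")
noise = protocol.NoiseModel(gaussian_sd_na=0.02, event_sd_na=0.0)
segments = [
    protocol.run_experiment(
        protocol.injection_script(1, seed=k, noise=noise, amplitude_na=-6.0),
        preset.params,
    ).holding_trace()
    for k in range(3)
]

for d in analysis.control_loop(segments, threshold_na=-11.0):
    print(f"attempt {d.segment_index}: drop {d.segment_drop_na:+.2f} nA, "
          f"cumulative {d.cumulative_drop_na:+.2f} nA -> {d.decision}")
print("(attempts accumulate; the loop stops at the first threshold crossing "
      "and the third prepared segment is never consumed)")
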