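"""Generate a synthetic isokinetic study and inspect its ground truth.

The generator emulates a 30-athlete protocol: reciprocal concentric/eccentric
knee extension and flexion at 60 deg/s, five maximal repetitions over a
0-90 deg range of knee flexion, with per-athlete intercepts, smooth shape
deviations, repetition offsets and measurement noise on top of known
population torque-angle curves.
"""

import isogamm as ig

df, truth = ig.simulate_dataset(ig.GeneratorConfig(seed=1))

print(f"rows simulated: {len(df)} "
      f"({truth.config.n_athletes} athletes x 4 action-modes x "
      f"{truth.config.n_repetitions} reps)")
print(f"constant-velocity fraction of each sweep: "
      f"{truth.constant_velocity_fraction:.3f}")
print(f"planted extension-ratio point of equality (flexion angle): "
      f"{truth.extension_ratio_crossings[0]:.1f} deg "
      f"(= {90 - truth.extension_ratio_crossings[0]:.1f} deg of extension progress)")
print("planted flexion-ratio extrema (angle, value, kind):")
for angle, value, kind in truth.flexion_ratio_extrema:
    print(f"  {angle:5.1f} deg  {value:.3f}  {kind}")

# preprocessing keeps only truly isokinetic samples and the best repetition
groups = ig.preprocess(df)
series = groups[("extension", "concentric")]
print(f"after preprocessing: {len(series)} athletes, "
      f"{len(series[0])} samples each for concentric extension")
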