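"""Read the learned correction off the attention maps.

Temporal: a refiner trained on +2-sample-shifted data should attend ~2
samples ahead of each output step.  Spatial: when the measured target is a
0.6/0.4 mixture of two simulated channels, the donor channel should rank
highly in the spatial attention weights.
"""

import numpy as np

from gaitrefine import (
    DistortionSpec, InputPattern, ModelConfig, build_pattern, generate_dataset,
    mix_target_channel, standardize, temporal_offset, top_k_muscles, train,
)

# --- temporal: +2-sample shift ---------------------------------------------
spec = DistortionSpec(temporal_shift=0.075, cycle_duration=0.75, noise_sd=0.02, seed=0)
pairs = generate_dataset(4, 4, 1, spec, seed=3, measurement_noise_sd=0.0)
pattern = InputPattern("One-Entire", "m00")
std, record = standardize([build_pattern(p, pattern) for p in pairs])
model = train(
    ModelConfig(input_channels=1, sequence_length=20, hidden_units=48, epochs=80, seed=0),
    std, normalization=record, pattern_name=pattern.name,
)
maps = [model.forward(s.input_sequence)[1] for s in std]
mean_w = np.mean([m.weights for m in maps], axis=0)
amap = maps[0]
amap.weights = mean_w / mean_w.sum(axis=1, keepdims=True)
summary = temporal_offset(amap)
print(f"injected shift: +2 samples; mean attention offset: {summary.mean_offset:+.2f} samples")
print("per-output-step attention argmax:", summary.argmax_steps.tolist())

# --- spatial: 0.6/0.4 donor mixture ----------------------------------------
spec = DistortionSpec(temporal_shift=0.0, noise_sd=0.02, seed=0)
pairs = mix_target_channel(
    generate_dataset(4, 4, 1, spec, seed=3, n_channels=12, measurement_noise_sd=0.0),
    "m00", "m05", (0.6, 0.4),
)
pattern = InputPattern("All-Entire", "m00")
std, record = standardize([build_pattern(p, pattern) for p in pairs])
model = train(
    ModelConfig(input_channels=12, sequence_length=20, hidden_units=48,
                attention_kind="spatial", epochs=80, seed=0),
    std, normalization=record, pattern_name=pattern.name,
)
maps = [model.forward(s.input_sequence)[1] for s in std]
mean_w = np.mean([m.weights for m in maps], axis=0)
amap = maps[0]
amap.weights = mean_w / mean_w.sum(axis=1, keepdims=True)
ranking = top_k_muscles(amap, k=5)
for frac in ranking.fractions:
    labels = ranking.labels_at(frac)
    print(f"top-5 muscles at {frac:.0%} of the cycle: {labels} "
          f"(donor m05 {'IN' if 'm05' in labels else 'not in'} top-5)")
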