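"""Walk the CNN discriminator's layer geometry for a 3120-sample input.

Each convolution layer's time-axis output length is floor((W-F+2P)/S)+1
and each max-pooling layer's is floor((W-F)/S)+1; the default architecture
chains two conv/pool pairs into a 50-feature flatten, a 25-unit fully
connected layer and a 2-way softmax.
"""

import numpy as np

from ecggan import DiscriminatorSpec, build_discriminator, conv_window_bounds

spec = DiscriminatorSpec.cnn_default(input_length=3120)
lengths = spec.layer_output_lengths()
names = ["C1 (conv 10x120, stride 5)", "P1 (pool 46, stride 3)",
         "C2 (conv 5x36, stride 3)", "P2 (pool 24, stride 3)"]
print("input length: 3120 samples")
for name, n in zip(names, lengths):
    print(f"  {name}: output length {n}")
print(f"flattened features: {spec.flat_features()} -> FC {spec.fc_units} -> softmax 2")

l, r = conv_window_bounds(i=1, k=5, h=120, T=3120)
print(f"first C1 filter window covers samples [{l}, {r}] (1-based)")
l, r = conv_window_bounds(i=601, k=5, h=120, T=3120)
print(f"last C1 filter window covers samples [{l}, {r}] — exactly reaching T")

disc = build_discriminator(spec, seed=0)
probs = disc(np.random.default_rng(0).normal(size=(3, 3120))).data
print("softmax pairs on random input (each row sums to 1):")
print(np.round(probs, 4))
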