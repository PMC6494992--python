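"""Train a reduced BiLSTM-CNN GAN on synthetic windows and sample from it.

Desk-scale settings (sequence 312 instead of 3120, 8 hidden units per
direction, a few epochs) so the example runs in well under a minute; the
full-scale reference settings are 500 epochs, batch 100, learning rate
1e-5 on 3120-sample windows.
"""

from ecggan import (
    DiscriminatorSpec,
    GANTrainConfig,
    GeneratorConfig,
    SynthConfig,
    generate_dataset,
    generate_ecgs,
    train_gan,
)

windows = generate_dataset(
    SynthConfig(duration=3120.0 / 360.0, seed=0), n_records=2, window_length=312
)
print(f"training pool: {len(windows)} windows of 312 samples")

gen_config = GeneratorConfig(noise_dim=5, seq_len=312, hidden_units=8, seed=0)
disc_spec = DiscriminatorSpec.scaled_cnn(312)
train_config = GANTrainConfig(
    epochs=5, batch_size=10, learning_rate=1e-3, seq_len=312, seed=0,
    non_saturating=True,
)
gen, disc, history = train_gan(gen_config, disc_spec, windows, train_config)
for epoch, (d, g) in enumerate(zip(history.d_losses, history.g_losses)):
    print(f"epoch {epoch}: d_loss={d:.4f} g_loss={g:.4f}")
print("(d_loss starts near 2 ln 2 ~ 1.386, the value when D outputs 0.5 everywhere)")

samples = generate_ecgs(gen, n=3, length=400, seed=1)
print(f"generated {samples.shape[0]} sequences of {samples.shape[1]} samples; "
      f"value range [{samples.min():.3f}, {samples.max():.3f}]")
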