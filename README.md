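# ecggan

Generative modelling of single-lead electrocardiogram (ECG) time series
with a bidirectional-LSTM generator trained adversarially against a 1-D
convolutional discriminator, plus the recurrent autoencoder baselines and
distortion metrics used to judge the generated signals.

Synthetic but realistic ECG data matters wherever model development needs
large labelled corpora that cannot be shared for privacy reasons: a
generator trained on clinical recordings can emit unlimited sequences that
follow the data distribution without exposing any patient. This package is
aimed at researchers in biomedical signal processing who want a compact,
fully inspectable NumPy implementation of that pipeline — every layer,
gradient and training step is ordinary Python, with no deep-learning
framework behind it.

## The model

The generator G maps Gaussian noise z (a T × d matrix, one d-dimensional
noise vector per time step) to a sequence, and the discriminator D maps a
sequence to a probability of being real. They play the minimax game

    min_G max_D  L = (1/N) Σ_i [ log D(x_i) + log(1 − D(G(z_i))) ]

- **Generator:** two bidirectional LSTM layers (100 cells per direction by
  default); each layer combines its forward and backward hidden states
  through a tanh affine map, followed by dropout (p = 0.5) and a
  time-distributed affine head emitting two values per step (time-step and
  lead elements). Training sequences are 3120 samples; generation uses
  noise dim 5 and any requested length (400 by default).
- **Discriminator:** a 1-D CNN over the 3120-sample lead channel:
  conv(10 filters × 120, stride 5) → maxpool(46, stride 3) →
  conv(5 × 36, stride 3) → maxpool(24, stride 3) → 50-feature flatten →
  fully connected 25 → 2-way softmax. Layer lengths follow
  floor((W − F + 2P)/S) + 1 for convolution and floor((W − F)/S) + 1 for
  pooling, giving 601 → 186 → 51 → 10. MLP, LSTM and GRU discriminators
  are available as comparison variants.
- **Baselines:** RNN/LSTM autoencoders and variational autoencoders over
  the same windows, with the reparameterization d = μ + σ ⊙ ε and the
  closed-form Gaussian KL term.
- **Metrics:** percent root mean square difference (PRD), root mean square
  error (RMSE), and the discrete Fréchet distance (FD) between sequences
  viewed as ordered (time, amplitude) curves, computed after min-max
  normalization.

Input handling covers the WFDB file family in its MIT-BIH dialect
(`.hea`/`.dat`/`.atr`, signal formats 212 and 16; raw samples divide by
the 200 adu/mV ADC gain) and plain delimited text with JSON sidecars. A
deterministic synthetic PQRST generator (five Gaussian bumps per cardiac
cycle plus seeded noise) stands in for clinical recordings so everything
is testable offline.

## Worked example

`python examples/discriminator_geometry.py` walks the discriminator's
shape arithmetic:

```
input length: 3120 samples
  C1 (conv 10x120, stride 5): output length 601
  P1 (pool 46, stride 3): output length 186
  C2 (conv 5x36, stride 3): output length 51
  P2 (pool 24, stride 3): output length 10
flattened features: 50 -> FC 25 -> softmax 2
first C1 filter window covers samples [1, 120] (1-based)
last C1 filter window covers samples [3001, 3120] — exactly reaching T
```

Each line is one layer of the CNN: 3120 samples shrink to 601 convolution
windows, 186 pooled values, and so on down to the 50 features entering the
classifier head. `python examples/evaluate_metrics.py` then scores two
mock generators against a synthetic pool:

```
near-copy    PRD=  14.517 RMSE=0.040 FD=0.099  (4 pairs, best pairing)
white noise  PRD= 116.763 RMSE=0.333 FD=0.532  (4 pairs, best pairing)
```

A generator that nearly copies the real windows scores an order of
magnitude better than white noise on all three distortion measures —
lower is better, and identical sequences would score exactly zero.

The other examples (`synthesize_records.py`, `train_small_gan.py`,
`autoencoder_baselines.py`) cover WFDB round trips, a desk-scale
adversarial training run, and the AE/VAE baselines. The same
functionality is scriptable through the CLI:

```sh
ecggan synth --records 2 --duration 30 --seed 1 --out data/
ecggan train --epochs 5 --seq-len 312 --hidden 8 --lr 1e-3 --out run/
ecggan generate --checkpoint run/generator.npz --n 4 --length 400 --out gen/
ecggan evaluate --real data/ --generated gen/ --out eval/
```

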