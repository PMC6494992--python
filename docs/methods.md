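# Methods

## Scope and model

The package implements adversarial generation of single-lead ECG
sequences. The generator is a stack of bidirectional LSTM layers; the
discriminator is, by default, a two-pair 1-D convolution/max-pooling
network ending in a 25-unit fully connected layer and a 2-way softmax,
with MLP/LSTM/GRU discriminators as variants. Training minimizes the
empirical two-player objective L = (1/N) Σ [log D(x) + log(1 − D(G(z)))]
by alternating one (configurable) discriminator step with one generator
step per mini-batch. Recurrent autoencoders (plain and variational, RNN
or LSTM cells) serve as non-adversarial baselines, and generated output
is scored with PRD, RMSE and the discrete Fréchet distance.

Everything runs on a small reverse-mode autodiff engine over NumPy arrays
(`ecggan.nn`). Each operation's backward rule is hand-derived and checked
against central finite differences in the test suite; recurrent layers
backpropagate through time via the tape. This keeps the package free of
deep-learning framework dependencies and makes every computation
inspectable, at the cost of speed — the intended regime is desk-scale
experiments, not GPU-scale training.

## Interpretation choices in the architecture

Several published details admit more than one reading; the package's
choices are:

- **"100 cells" per BiLSTM layer** is read as 100 hidden units *per
  direction*, the standard BiLSTM convention, so the combined per-step
  state is 200 wide. Each layer's output is tanh(W_f h_fwd + W_b h_bwd +
  b), an affine tanh combination of the two directions' states, of width
  2 × hidden. The affine output head is shared across time steps.
- **Noise input** is a T × d matrix of standard-Gaussian vectors
  (d = 5 at generation time). Descriptions of the noise as "one-hot" are
  treated as a misnomer; Gaussian sampling is what the model family uses.
- **Generator output** has two channels per step (time-step element and
  lead element) following the music-GAN representation it derives from;
  only the lead channel is fed to the discriminator, whose input is a
  single 3120-sample channel.
- **Softmax head**: the discriminator's classifier is a 25 → 2 affine map
  with a 2-class softmax; the probability-of-real is the first component
  and binary decisions take the argmax. A published layer table lists a
  25 → 25 softmax row instead; the 2-class reading is the only one
  consistent with the accompanying softmax formula (explicitly summing
  over k = 1..2) and is what is implemented.
- **Convolution nonlinearity** f in c_i = f(w·x_{l:r} + b) is unnamed in
  the source description; LeakyReLU with slope 0.2 is used, configurable.
- **Min-max normalization** before metric computation defaults to [0, 1]
  scaling. The formula as typeset, (x − x_max)/(x_max − x_min), maps onto
  [−1, 0] instead and is almost certainly a sign typo; it is kept as an
  `as_printed` mode.
- **PRD** likewise defaults to the standard form 100·sqrt(Σe²/Σx²), with
  an `as_printed` mode that keeps the factor 100 inside the radical.
- **VAE objective**: the KL term's sign in the published ELBO is
  ambiguous as typeset; the standard negative ELBO (reconstruction MSE
  plus closed-form Gaussian KL, ½Σ(μ² + σ² − 1 − 2 ln σ)) is implemented
  as a loss to minimize. The AE's log-likelihood objective is realized as
  unit-variance Gaussian likelihood, reported as its MSE equivalent.
- **Pairing protocol for metrics**: generated sequences come from noise
  and have no designated reference, and no published protocol states how
  they are paired for PRD/RMSE/FD. The default pairs each generated
  sequence with the real window minimizing RMSE against it ("best"
  pairing); "fixed" index pairing is available for reproducible tests.
  This is the largest genuinely open choice in the pipeline.

## Parameters and defaults

| Parameter | Default | Meaning |
|---|---|---|
| seq_len | 3120 samples | training window (~8.7 s at 360 Hz) |
| noise_dim d | 5 | per-step noise vector width |
| hidden_units | 100/direction | generator BiLSTM size |
| dropout_p | 0.5 | generator dropout |
| epochs / batch / lr | 500 / 100 / 1e-5 | full-scale reference settings |
| optimizer | Adam | only the learning rate is prescribed upstream |
| ADC gain | 200 adu/mV | MIT-BIH scaling; raw samples divide by it |
| clamp ε | 1e-7 | probability clamp before logs |

Losses are logged as per-epoch means over mini-batches. Training is
deterministic given the config seed: parameter initialization, batch
shuffling, noise draws and dropout masks all derive from it.

## Synthetic data generator

`synth_ecg` renders each cardiac cycle as five Gaussian bumps on the
cycle phase θ ∈ [0, 2π) — amplitudes (0.12, −0.10, 1.00, −0.17, 0.25) mV
at positions (π−π/3, π−π/12, π, π+π/12, π+π/2) with widths (0.25, 0.1,
0.1, 0.1, 0.4) rad — plus seeded white Gaussian noise (default SD
0.05 mV) and an optional low-frequency baseline sinusoid. Defaults are
60 bpm at 360 Hz, the MIT-BIH sampling rate. A static sum-of-Gaussians
was chosen over integrating the classic three-ODE dynamical ECG model:
it is deterministic, trivially seeded, and reproduces the PQRST
morphology and periodicity that the pipeline's statistics depend on.

What it does *not* emulate: beat-to-beat RR variability, arrhythmic
morphologies, electrode artefacts, and multi-lead correlation. Passing
tests on this fixture therefore demonstrate the correctness of the
machinery (shapes, gradients, losses, metrics, reproducibility), not
clinical fidelity of generated ECGs on real patient data.

## Desk-scale experiment sizes

The package's own experiments and tests run on one CPU at reduced sizes:
sequence 312 (one tenth of full scale) with a proportionally scaled CNN
(filters 12 and 4, pools 5 and 2, strides kept), generator hidden size
8–16, pools of tens of windows, and tens of epochs. At these sizes the
full-scale settings (lr 1e-5, saturating generator loss) barely move the
parameters, so the desk-scale training demonstration uses Adam at 1e-3
with the non-saturating generator objective −log D(G(z)) — the standard
practical variant, provided alongside the saturating form — under which
the discriminator measurably learns and a 20-epoch generator improves its
best-match RMSE against the training pool over an untrained one. Loss
values reported for full equilibrium remain exact: at D ≡ 0.5 the
discriminator loss is 2 ln 2.

## Numerical choices and degenerate inputs

- Probabilities are clamped to [1e-7, 1 − 1e-7] before logs (scalar
  losses) or offset by the same ε inside the graph (training losses).
- Min-max normalization of a constant sequence raises a degenerate-input
  error rather than dividing by zero; PRD of an all-zero reference
  likewise.
- The discrete Fréchet DP fills the full coupling lattice in
  O(|P|·|Q|); ties in max/min resolve by first occurrence (NumPy argmax
  semantics in pooling; order of min() arguments in the DP), which does
  not affect the distance value. An exhaustive coupling enumeration is
  shipped as an oracle and the two are tested to agree exactly on small
  curves.
- Sequences of unequal length are truncated to the shortest before batch
  evaluation; windows are half-open, 0-based, and any trailing partial
  window is discarded.
- Weight init is uniform ±1/sqrt(fan-in) from the model's seeded
  generator; LSTM/GRU gates use one fused affine map per step.
- WFDB support covers the MIT-BIH subset: formats 212 and 16, one data
  file per record, per-signal checksum verification, and the common beat
  annotation codes (with SKIP intervals); it is a purpose-built reader,
  not a general WFDB implementation, and round-trips are tested against
  the package's own writer.

## Known limitations

- Pure-NumPy training is orders of magnitude slower than a GPU framework;
  full-scale runs (500 epochs × 48 records × 208 windows of 3120 samples)
  are out of desk reach, so published full-scale metric tables cannot be
  reproduced here and are not claimed.
- The recurrent discriminators process long sequences step-by-step and
  are practical only at reduced sequence lengths.
- Free-running autoencoder decoding can drift for long horizons; teacher
  forcing is used during training.
- Adversarial training at desk scale is sensitive to the learning rate
  and objective variant, as is typical for small GANs.
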