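"""Recurrent autoencoder baselines: RNN-AE, LSTM-AE, RNN-VAE, LSTM-VAE.

The encoder runs a recurrent cell over the input sequence and maps its
final hidden state to a latent code d (for the variational models, to a
mean and standard-deviation pair combined by the reparameterization trick
d = mu + sigma * eps).  The decoder is a recurrent cell whose input at
every step is the latent code concatenated with the previous output —
the ground-truth previous sample under teacher forcing during training,
the model's own previous output when free-running.

The reconstruction objective is a unit-variance Gaussian log-likelihood,
reported as its monotone equivalent, mean squared error; the variational
loss adds the closed-form KL divergence to the standard-normal prior and
is returned as a negative evidence lower bound (a loss to minimize).
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .errors import ShapeError, ValidationError
from .nn import Adam, Dense, LSTM, Module, Tensor, VanillaRNN, concatenate, tensor
from .training import TrainHistory, _windows_to_array

__all__ = [
    "AEConfig",
    "reparameterize",
    "gaussian_kl",
    "ae_loss",
    "vae_loss",
    "RecurrentAutoencoder",
    "train_autoencoder",
]


@dataclass
class AEConfig:
    """Hyperparameters of a recurrent (variational) autoencoder."""

    cell: str = "lstm"  # "rnn" or "lstm"
    hidden_units: int = 32
    latent_dim: int = 8
    seq_len: int = 3120
    variational: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.cell not in ("rnn", "lstm"):
            raise ValidationError(f"unknown cell type {self.cell!r}")
        if self.hidden_units < 1:
            raise ValidationError(
                f"hidden_units must be >= 1, got {self.hidden_units}"
            )
        if self.latent_dim < 1:
            raise ValidationError(f"latent_dim must be >= 1, got {self.latent_dim}")
        if self.seq_len < 1:
            raise ValidationError(f"seq_len must be >= 1, got {self.seq_len}")

    def to_dict(self) -> dict:
        return {
            "cell": self.cell,
            "hidden_units": self.hidden_units,
            "latent_dim": self.latent_dim,
            "seq_len": self.seq_len,
            "variational": self.variational,
            "seed": self.seed,
        }


def reparameterize(mu, sigma, eps=None, seed: Optional[int] = None):
    """Latent draw d = mu + sigma * eps with eps ~ N(0, 1).

    `eps` may be supplied explicitly (for determinism); otherwise it is
    drawn from a generator seeded with `seed`.
    """
    mu = np.asarray(mu, dtype=np.float64)
    sigma = np.asarray(sigma, dtype=np.float64)
    if mu.shape != sigma.shape:
        raise ShapeError(f"mu shape {mu.shape} != sigma shape {sigma.shape}")
    if np.any(sigma < 0):
        raise ValidationError("sigma must be elementwise >= 0")
    if eps is None:
        eps = np.random.default_rng(seed).standard_normal(mu.shape)
    else:
        eps = np.asarray(eps, dtype=np.float64)
        if eps.shape != mu.shape:
            raise ShapeError(f"eps shape {eps.shape} != mu shape {mu.shape}")
    return mu + sigma * eps


def gaussian_kl(mu, sigma) -> float:
    """KL(N(mu, diag(sigma^2)) || N(0, I)) = 1/2 sum(mu^2 + sigma^2 - 1 - 2 ln sigma).

    For batched (batch, latent) inputs the per-sample KL is averaged over
    the batch.  Zero iff mu = 0 and sigma = 1 elementwise.
    """
    mu = np.asarray(mu, dtype=np.float64)
    sigma = np.asarray(sigma, dtype=np.float64)
    if mu.shape != sigma.shape:
        raise ShapeError(f"mu shape {mu.shape} != sigma shape {sigma.shape}")
    if np.any(sigma <= 0):
        raise ValidationError("sigma must be elementwise > 0")
    kl = 0.5 * (mu ** 2 + sigma ** 2 - 1.0 - 2.0 * np.log(sigma))
    per_sample = kl.sum(axis=-1)
    return float(np.mean(per_sample))


def ae_loss(inputs, reconstructions) -> float:
    """Reconstruction objective as its MSE equivalent.

    Maximizing the per-point Gaussian log-likelihood of the decoder output
    is equivalent (up to additive/multiplicative constants) to minimizing
    the mean squared error, which is the comparable scalar reported here.
    """
    x = np.asarray(inputs, dtype=np.float64)
    y = np.asarray(reconstructions, dtype=np.float64)
    if x.shape != y.shape:
        raise ShapeError(f"shape mismatch: {x.shape} vs {y.shape}")
    if x.size == 0:
        raise ValidationError("inputs must be non-empty")
    return float(np.mean((x - y) ** 2))


def vae_loss(inputs, reconstructions, mu, sigma) -> float:
    """Negative evidence lower bound: reconstruction MSE plus the Gaussian
    KL to the standard-normal prior (a loss to minimize)."""
    return ae_loss(inputs, reconstructions) + gaussian_kl(mu, sigma)


class RecurrentAutoencoder(Module):
    """Sequence autoencoder with RNN or LSTM encoder and decoder."""

    def __init__(self, config: AEConfig):
        super().__init__()
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        cell_cls = LSTM if config.cell == "lstm" else VanillaRNN
        self.encoder = self.add_module("encoder", cell_cls(1, config.hidden_units, rng))
        head_out = 2 * config.latent_dim if config.variational else config.latent_dim
        self.latent_head = self.add_module(
            "latent_head", Dense(config.hidden_units, head_out, rng)
        )
        self.decoder = self.add_module(
            "decoder", cell_cls(config.latent_dim + 1, config.hidden_units, rng)
        )
        self.out_head = self.add_module("out_head", Dense(config.hidden_units, 1, rng))
        self._noise_rng = np.random.default_rng(int(rng.integers(0, 2 ** 31)))

    def encode(self, x: Tensor) -> Tuple[Tensor, Optional[Tensor]]:
        """Return (latent code, sigma); sigma is None for the plain AE.

        For the VAE the head emits mu and log sigma; sigma = exp(log sigma)
        and, in training mode, the code is the reparameterized draw
        mu + sigma * eps (the mean in eval mode).
        """
        h_last = self.encoder.last_hidden(x)
        z = self.latent_head(h_last)
        if not self.config.variational:
            return z, None
        k = self.config.latent_dim
        mu = z[:, :k]
        sigma = z[:, k:].exp()
        if self.training:
            eps = self._noise_rng.standard_normal(mu.shape)
            code = mu + sigma * Tensor(eps)
        else:
            code = mu
        return code, (mu, sigma)

    def decode(self, code: Tensor, seq_len: int, targets: Optional[Tensor] = None) -> Tensor:
        """Roll the decoder for seq_len steps.

        With `targets` given, the previous output fed at each step is the
        ground-truth previous sample (teacher forcing); otherwise the
        model's own previous output (free-running).  Returns (batch, T).
        """
        batch = code.shape[0]
        state = self.decoder._init_state(batch)
        prev = Tensor(np.zeros((batch, 1)))
        outputs: List[Tensor] = []
        for t in range(seq_len):
            step_in = concatenate([code, prev], axis=1)
            h, state = self.decoder._step(step_in, state)
            y = self.out_head(h)  # (batch, 1)
            outputs.append(y)
            if targets is not None:
                prev = targets[:, t : t + 1]
            else:
                prev = y
        return concatenate(outputs, axis=1)

    def __call__(self, x, teacher_forcing: Optional[bool] = None):
        """Encode and reconstruct a (batch, T) batch.

        Returns (reconstruction, mu, sigma); mu and sigma are None for the
        non-variational model.  Teacher forcing defaults to the training
        mode flag.
        """
        x = tensor(x)
        if x.ndim != 2:
            raise ShapeError(f"expected (batch, T) input, got {x.shape}")
        batch, T = x.shape
        if teacher_forcing is None:
            teacher_forcing = self.training
        code, musigma = self.encode(x.reshape(batch, T, 1))
        recon = self.decode(code, T, targets=x if teacher_forcing else None)
        if musigma is None:
            return recon, None, None
        return recon, musigma[0], musigma[1]


def train_autoencoder(
    config: AEConfig,
    data,
    epochs: int = 500,
    batch_size: int = 100,
    lr: float = 1e-5,
    seed: int = 0,
) -> Tuple[RecurrentAutoencoder, TrainHistory]:
    """Train an (variational) autoencoder; per-epoch mean losses recorded.

    The recorded loss is the MSE equivalent (plus the KL term for the
    variational models), so curves of the four baselines are directly
    comparable.
    """
    config.validate()
    if epochs < 1 or batch_size < 1:
        raise ValidationError("epochs and batch_size must be >= 1")
    x = _windows_to_array(data, config.seq_len)
    n = len(x)
    rng = np.random.default_rng(seed)
    model = RecurrentAutoencoder(config)
    opt = Adam(model.parameters(), lr=lr)
    history = TrainHistory(
        config={**config.to_dict(), "epochs": epochs, "batch_size": batch_size, "lr": lr},
        seed=seed,
    )
    start = time.perf_counter()
    for _ in range(epochs):
        order = rng.permutation(n)
        losses: List[float] = []
        for lo in range(0, n, batch_size):
            batch = x[order[lo : lo + batch_size]]
            model.train()
            recon, mu, sigma = model(batch)
            diff = recon - Tensor(batch)
            loss = (diff * diff).mean(axis=1).mean()
            if config.variational:
                kl = (
                    (mu * mu + sigma * sigma - 2.0 * sigma.log() - 1.0)
                    .sum(axis=1)
                    .mean()
                    * 0.5
                )
                loss = loss + kl
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history.append(float(np.mean(losses)), 0.0)
    history.wall_clock_seconds = time.perf_counter() - start
    model.eval()
    return model, history
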