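"""Adversarial training of the BiLSTM generator against a discriminator.

The minimax objective is the empirical two-player loss
L = (1/N) sum_i [log D(x_i) + log(1 - D(G(z_i)))]: the discriminator
ascends it (we minimize its negation) and the generator descends
log(1 - D(G(z))), with an optional non-saturating variant that instead
minimizes -log D(G(z)).  Updates alternate per mini-batch, a configurable
number of discriminator steps per generator step.
"""

from __future__ import annotations

import csv
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .ecg_io import SequenceWindow
from .errors import ValidationError
from .models import (
    DiscriminatorSpec,
    Generator,
    GeneratorConfig,
    build_discriminator,
    build_generator,
)
from .nn import Adam, SGD, Tensor

logger = logging.getLogger(__name__)

__all__ = [
    "GANTrainConfig",
    "TrainHistory",
    "gan_losses",
    "sample_noise",
    "train_gan",
    "generate_ecgs",
    "CLAMP_EPS",
]

#: Probabilities are clamped to [CLAMP_EPS, 1 - CLAMP_EPS] before taking logs.
CLAMP_EPS = 1e-7


@dataclass
class GANTrainConfig:
    """Adversarial training hyperparameters.

    Reference settings: 500 epochs, mini-batch 100, learning rate 1e-5,
    sequence length 3120.  Adam is used; the reference work names only the
    learning rate.
    """

    epochs: int = 500
    batch_size: int = 100
    learning_rate: float = 1e-5
    seq_len: int = 3120
    d_steps_per_g_step: int = 1
    seed: int = 0
    optimizer: str = "adam"
    non_saturating: bool = False

    def validate(self) -> None:
        for name in ("epochs", "batch_size", "seq_len", "d_steps_per_g_step"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.learning_rate <= 0:
            raise ValidationError(
                f"learning_rate must be > 0, got {self.learning_rate}"
            )
        if self.optimizer not in ("adam", "sgd"):
            raise ValidationError(f"unknown optimizer {self.optimizer!r}")

    def to_dict(self) -> dict:
        return {
            "epochs": self.epochs,
            "batch_size": self.batch_size,
            "learning_rate": self.learning_rate,
            "seq_len": self.seq_len,
            "d_steps_per_g_step": self.d_steps_per_g_step,
            "seed": self.seed,
            "optimizer": self.optimizer,
            "non_saturating": self.non_saturating,
        }


@dataclass
class TrainHistory:
    """Per-epoch loss log with the config snapshot and seed that produced it."""

    d_losses: List[float] = field(default_factory=list)
    g_losses: List[float] = field(default_factory=list)
    config: dict = field(default_factory=dict)
    seed: int = 0
    wall_clock_seconds: float = 0.0

    @property
    def n_epochs(self) -> int:
        return len(self.d_losses)

    def append(self, d_loss: float, g_loss: float) -> None:
        if not (np.isfinite(d_loss) and np.isfinite(g_loss)):
            raise ValidationError(
                f"non-finite epoch losses: d={d_loss}, g={g_loss}"
            )
        self.d_losses.append(float(d_loss))
        self.g_losses.append(float(g_loss))

    def to_csv(self, path) -> Path:
        path = Path(path)
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["epoch", "d_loss", "g_loss"])
            for i, (d, g) in enumerate(zip(self.d_losses, self.g_losses)):
                writer.writerow([i, f"{d:.10g}", f"{g:.10g}"])
        return path


def _clamp_probs(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=np.float64)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        logger.warning(
            "probabilities at or beyond {0, 1} clamped to [%g, %g]",
            CLAMP_EPS,
            1 - CLAMP_EPS,
        )
    return np.clip(p, CLAMP_EPS, 1.0 - CLAMP_EPS)


def gan_losses(
    d_real, d_fake, non_saturating: bool = False
) -> Tuple[float, float]:
    """Scalar discriminator and generator losses from probability batches.

    d_loss = -(1/N) sum [log d_real_i + log(1 - d_fake_i)] — the negation
    of the minimax value the discriminator maximizes.  g_loss =
    (1/N) sum log(1 - d_fake_i) (saturating, the generator's descent
    target); with non_saturating=True, -(1/N) sum log d_fake_i instead.
    """
    d_real = _clamp_probs(d_real)
    d_fake = _clamp_probs(d_fake)
    if d_real.shape != d_fake.shape:
        raise ValidationError(
            f"batch sizes differ: {d_real.shape} vs {d_fake.shape}"
        )
    d_loss = -float(np.mean(np.log(d_real) + np.log(1.0 - d_fake)))
    if non_saturating:
        g_loss = -float(np.mean(np.log(d_fake)))
    else:
        g_loss = float(np.mean(np.log(1.0 - d_fake)))
    return d_loss, g_loss


def sample_noise(
    batch: int, T: int, d: int, seed: Optional[Union[int, np.random.Generator]] = None
) -> np.ndarray:
    """(batch, T, d) standard-Gaussian noise; deterministic per seed."""
    if batch < 1 or T < 1 or d < 1:
        raise ValidationError(
            f"noise dimensions must be positive, got ({batch}, {T}, {d})"
        )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    return rng.standard_normal((batch, T, d))


def _windows_to_array(data: Sequence, seq_len: int) -> np.ndarray:
    rows = []
    for w in data:
        values = w.values if isinstance(w, SequenceWindow) else np.asarray(w)
        if len(values) != seq_len:
            raise ValidationError(
                f"window length {len(values)} does not match seq_len {seq_len}"
            )
        rows.append(np.asarray(values, dtype=np.float64))
    if not rows:
        raise ValidationError("training data is empty")
    return np.stack(rows)


def _log_term(p: Tensor) -> Tensor:
    # log with additive epsilon; keeps the graph differentiable at p ~ 0.
    return (p + CLAMP_EPS).log()


def train_gan(
    gen_config: GeneratorConfig,
    disc_spec: DiscriminatorSpec,
    data: Sequence,
    train_config: GANTrainConfig,
) -> Tuple[Generator, object, TrainHistory]:
    """Alternating adversarial training; fully reproducible per seed.

    `data` is a sequence of SequenceWindow or arrays, all of length
    train_config.seq_len (which must equal both the generator's seq_len
    and the discriminator's input_length).  Returns the trained generator
    and discriminator plus the per-epoch mean-loss history.
    """
    train_config.validate()
    gen_config.validate()
    disc_spec.validate()
    if gen_config.seq_len != train_config.seq_len:
        raise ValidationError(
            f"generator seq_len {gen_config.seq_len} != training seq_len "
            f"{train_config.seq_len}"
        )
    if disc_spec.input_length != train_config.seq_len:
        raise ValidationError(
            f"discriminator input_length {disc_spec.input_length} != "
            f"training seq_len {train_config.seq_len}"
        )
    real = _windows_to_array(data, train_config.seq_len)
    n = len(real)

    rng = np.random.default_rng(train_config.seed)
    gen = build_generator(gen_config)
    disc = build_discriminator(disc_spec, seed=int(rng.integers(0, 2 ** 31)))
    opt_cls = Adam if train_config.optimizer == "adam" else SGD
    g_opt = opt_cls(gen.parameters(), lr=train_config.learning_rate)
    d_opt = opt_cls(disc.parameters(), lr=train_config.learning_rate)

    history = TrainHistory(config=train_config.to_dict(), seed=train_config.seed)
    start = time.perf_counter()
    for epoch in range(train_config.epochs):
        order = rng.permutation(n)
        epoch_d: List[float] = []
        epoch_g: List[float] = []
        for lo in range(0, n, train_config.batch_size):
            batch_idx = order[lo : lo + train_config.batch_size]
            real_batch = real[batch_idx]
            m = len(batch_idx)

            for _ in range(train_config.d_steps_per_g_step):
                noise = sample_noise(m, train_config.seq_len, gen_config.noise_dim, rng)
                gen.eval()
                fake = gen.lead_channel(gen(noise)).detach()
                disc.train()
                p_real = disc(real_batch)[:, 0]
                p_fake = disc(fake)[:, 0]
                d_loss_t = -(
                    _log_term(p_real).mean() + _log_term(1.0 - p_fake).mean()
                )
                d_opt.zero_grad()
                d_loss_t.backward()
                d_opt.step()
                epoch_d.append(float(d_loss_t.data))

            noise = sample_noise(m, train_config.seq_len, gen_config.noise_dim, rng)
            gen.train()
            disc.eval()
            fake = gen.lead_channel(gen(noise))
            p_fake = disc(fake)[:, 0]
            if train_config.non_saturating:
                g_loss_t = -_log_term(p_fake).mean()
            else:
                g_loss_t = _log_term(1.0 - p_fake).mean()
            g_opt.zero_grad()
            disc.zero_grad()
            g_loss_t.backward()
            g_opt.step()
            epoch_g.append(float(g_loss_t.data))

        history.append(float(np.mean(epoch_d)), float(np.mean(epoch_g)))
        logger.info(
            "epoch %d: d_loss=%.6f g_loss=%.6f",
            epoch,
            history.d_losses[-1],
            history.g_losses[-1],
        )
    history.wall_clock_seconds = time.perf_counter() - start
    gen.eval()
    disc.eval()
    return gen, disc, history


def generate_ecgs(
    generator: Generator,
    n: int,
    length: int = 400,
    noise_dim: Optional[int] = None,
    seed: int = 0,
) -> np.ndarray:
    """Sample `n` lead sequences of `length` samples from the generator.

    The generator's time-distributed layers accept any sequence length, so
    shorter generation lengths (e.g. 400, or the quality optimum 250) work
    with a model trained at 3120.  Only the lead channel is returned.
    """
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    if length < 1:
        raise ValidationError(f"length must be >= 1, got {length}")
    d = generator.config.noise_dim
    if noise_dim is not None and noise_dim != d:
        raise ValidationError(
            f"noise_dim {noise_dim} does not match generator noise_dim {d}"
        )
    generator.eval()
    noise = sample_noise(n, length, d, seed)
    return generator.lead_channel(generator(noise)).data
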