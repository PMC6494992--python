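"""Generator and discriminator architectures.

The generator is a stack of two bidirectional LSTM layers (100 cells per
direction by default), a dropout layer, and a time-distributed affine head
emitting two values per step (time-step element and lead element).  The
reference discriminator is a 1-D CNN with two convolution/max-pooling
pairs, a 25-unit fully connected layer, and a 2-way softmax; MLP, LSTM and
GRU discriminators are provided as comparison variants.

The convolution/pooling output-length formulas and the 1-based window
bounds of the sliding filter are exposed as plain functions so the layer
geometry can be checked independently of any network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple, Union

import numpy as np

from .errors import ShapeError, ValidationError
from .nn import (
    BiLSTMLayer,
    Dense,
    Dropout,
    GRU,
    LSTM,
    Module,
    Tensor,
    conv1d,
    concatenate,
    maxpool1d,
    softmax,
    tensor,
)

__all__ = [
    "GeneratorConfig",
    "ConvLayerSpec",
    "PoolLayerSpec",
    "DiscriminatorSpec",
    "conv_output_length",
    "pool_output_length",
    "conv_window_bounds",
    "build_generator",
    "build_discriminator",
    "discriminator_forward",
    "Generator",
    "CNNDiscriminator",
    "MLPDiscriminator",
    "RecurrentDiscriminator",
]


# ---------------------------------------------------------------------------
# Shape arithmetic
# ---------------------------------------------------------------------------


def conv_output_length(W: int, F: int, S: int, P: int = 0) -> int:
    """Output length of a valid 1-D convolution: floor((W - F + 2P)/S) + 1."""
    if S < 1:
        raise ValidationError(f"stride must be >= 1, got {S}")
    if P < 0:
        raise ValidationError(f"zero padding must be >= 0, got {P}")
    if W + 2 * P < F:
        raise ShapeError(
            f"input length {W} with padding {P} is shorter than filter {F}"
        )
    return (W - F + 2 * P) // S + 1


def pool_output_length(W: int, F: int, S: int) -> int:
    """Output length of 1-D pooling: floor((W - F)/S) + 1."""
    if S < 1:
        raise ValidationError(f"stride must be >= 1, got {S}")
    if W < F:
        raise ShapeError(f"input length {W} is shorter than pooling window {F}")
    return (W - F) // S + 1


def conv_window_bounds(i: int, k: int, h: int, T: int) -> Tuple[int, int]:
    """1-based inclusive bounds (l, r) of the i-th filter window:
    l = k*i + 1 - k, r = k*i - k + h."""
    n_windows = (T - h) // k + 1
    if not 1 <= i <= n_windows:
        raise IndexError(
            f"window index {i} out of range [1, {n_windows}] for "
            f"T={T}, h={h}, k={k}"
        )
    l = k * i + 1 - k
    r = k * i - k + h
    return l, r


# ---------------------------------------------------------------------------
# Configuration dataclasses
# ---------------------------------------------------------------------------


@dataclass
class GeneratorConfig:
    """Hyperparameters of the BiLSTM generator.

    noise_dim is the per-time-step width d of the Gaussian noise vector
    (5 at generation time); seq_len is the sequence length T (3120 for
    training, 400 for generation); hidden_units is the LSTM cell count per
    direction per layer.
    """

    noise_dim: int = 5
    seq_len: int = 3120
    hidden_units: int = 100
    n_bilstm_layers: int = 2
    dropout_p: float = 0.5
    output_dim: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.noise_dim < 1:
            raise ValidationError(f"noise_dim must be >= 1, got {self.noise_dim}")
        if self.seq_len < 1:
            raise ValidationError(f"seq_len must be >= 1, got {self.seq_len}")
        if self.hidden_units < 1:
            raise ValidationError(
                f"hidden_units must be >= 1, got {self.hidden_units}"
            )
        if self.n_bilstm_layers < 1:
            raise ValidationError(
                f"n_bilstm_layers must be >= 1, got {self.n_bilstm_layers}"
            )
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValidationError(
                f"dropout_p must be in [0, 1), got {self.dropout_p}"
            )
        if self.output_dim < 1:
            raise ValidationError(f"output_dim must be >= 1, got {self.output_dim}")


@dataclass
class ConvLayerSpec:
    """One convolutional layer: M filters of length h, stride k, padding P."""

    n_filters: int
    filter_length: int
    stride: int
    zero_padding: int = 0

    def validate(self) -> None:
        if self.n_filters < 1:
            raise ValidationError(f"n_filters must be >= 1, got {self.n_filters}")
        if not 1 <= self.stride <= self.filter_length:
            raise ValidationError(
                f"stride must satisfy 1 <= k <= h, got k={self.stride}, "
                f"h={self.filter_length}"
            )
        if self.zero_padding < 0:
            raise ValidationError(
                f"zero_padding must be >= 0, got {self.zero_padding}"
            )


@dataclass
class PoolLayerSpec:
    """One max-pooling layer: window a, stride b."""

    window: int
    stride: int

    def validate(self) -> None:
        if self.window < 1 or self.stride < 1:
            raise ValidationError(
                f"pool window and stride must be >= 1, got a={self.window}, "
                f"b={self.stride}"
            )


def _table1_layers() -> List[Union[ConvLayerSpec, PoolLayerSpec]]:
    return [
        ConvLayerSpec(n_filters=10, filter_length=120, stride=5, zero_padding=0),
        PoolLayerSpec(window=46, stride=3),
        ConvLayerSpec(n_filters=5, filter_length=36, stride=3, zero_padding=0),
        PoolLayerSpec(window=24, stride=3),
    ]


@dataclass
class DiscriminatorSpec:
    """Architecture bundle for a discriminator.

    kind "cnn" uses `layers` (alternating conv/pool specs), then a fully
    connected layer of `fc_units`, then a 2-way softmax.  Kinds "mlp",
    "lstm" and "gru" use `hidden_sizes` instead.
    """

    kind: str = "cnn"
    input_length: int = 3120
    layers: List[Union[ConvLayerSpec, PoolLayerSpec]] = field(
        default_factory=_table1_layers
    )
    fc_units: int = 25
    hidden_sizes: Tuple[int, ...] = (64, 32)
    leaky_slope: float = 0.2

    def validate(self) -> None:
        if self.kind not in ("cnn", "mlp", "lstm", "gru"):
            raise ValidationError(f"unknown discriminator kind {self.kind!r}")
        if self.input_length < 1:
            raise ValidationError(
                f"input_length must be >= 1, got {self.input_length}"
            )
        if self.kind == "cnn":
            for layer in self.layers:
                layer.validate()
            self.layer_output_lengths()  # raises ShapeError if inconsistent
            if self.fc_units < 1:
                raise ValidationError(f"fc_units must be >= 1, got {self.fc_units}")
        else:
            if not self.hidden_sizes:
                raise ValidationError("hidden_sizes must be non-empty")

    def layer_output_lengths(self) -> List[int]:
        """Time-axis output length after each conv/pool layer in order."""
        lengths = []
        current = self.input_length
        for layer in self.layers:
            if isinstance(layer, ConvLayerSpec):
                current = conv_output_length(
                    current, layer.filter_length, layer.stride, layer.zero_padding
                )
            else:
                current = pool_output_length(current, layer.window, layer.stride)
            lengths.append(current)
        return lengths

    def flat_features(self) -> int:
        """Features entering the fully connected layer (channels x length)."""
        channels = 1
        for layer in self.layers:
            if isinstance(layer, ConvLayerSpec):
                channels = layer.n_filters
        return channels * self.layer_output_lengths()[-1]

    @classmethod
    def cnn_default(cls, input_length: int = 3120) -> "DiscriminatorSpec":
        """The reference two-pair CNN geometry for 3120-sample input."""
        return cls(kind="cnn", input_length=input_length, layers=_table1_layers())

    @classmethod
    def scaled_cnn(cls, input_length: int) -> "DiscriminatorSpec":
        """Reference geometry with filter/window sizes scaled proportionally
        to a shorter input, for desk-scale experiments."""
        scale = input_length / 3120.0
        layers: List[Union[ConvLayerSpec, PoolLayerSpec]] = []
        for layer in _table1_layers():
            if isinstance(layer, ConvLayerSpec):
                h = max(1, round(layer.filter_length * scale))
                layers.append(
                    ConvLayerSpec(
                        n_filters=layer.n_filters,
                        filter_length=h,
                        stride=min(layer.stride, h),
                        zero_padding=0,
                    )
                )
            else:
                layers.append(
                    PoolLayerSpec(
                        window=max(1, round(layer.window * scale)),
                        stride=layer.stride,
                    )
                )
        spec = cls(kind="cnn", input_length=input_length, layers=layers)
        spec.validate()
        return spec


# ---------------------------------------------------------------------------
# Generator
# ---------------------------------------------------------------------------


class Generator(Module):
    """BiLSTM sequence generator.

    Maps a (batch, T, noise_dim) Gaussian noise tensor to a
    (batch, T, output_dim) sequence.  Each BiLSTM layer combines its
    forward and backward hidden states through a tanh affine map; the head
    is a time-distributed affine layer shared across time steps.  Initial
    hidden states are zero vectors.
    """

    def __init__(self, config: GeneratorConfig):
        super().__init__()
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        in_features = config.noise_dim
        self.bilstm_layers: List[BiLSTMLayer] = []
        for i in range(config.n_bilstm_layers):
            layer = BiLSTMLayer(in_features, config.hidden_units, rng)
            self.add_module(f"bilstm{i}", layer)
            self.bilstm_layers.append(layer)
            in_features = layer.out_features
        self.dropout = self.add_module(
            "dropout",
            Dropout(config.dropout_p, seed=int(rng.integers(0, 2 ** 31))),
        )
        self.head = self.add_module(
            "head", Dense(in_features, config.output_dim, rng)
        )

    def __call__(self, noise) -> Tensor:
        x = tensor(noise)
        if x.ndim != 3 or x.shape[2] != self.config.noise_dim:
            raise ShapeError(
                f"noise must be (batch, T, {self.config.noise_dim}), "
                f"got {x.shape}"
            )
        for layer in self.bilstm_layers:
            x = layer(x)
        x = self.dropout(x)
        return self.head(x)

    def lead_channel(self, output: Tensor) -> Tensor:
        """Extract the lead element (channel 1) of the 2-dim output, the
        part the discriminator consumes."""
        return output[:, :, 1]


def build_generator(config: GeneratorConfig) -> Generator:
    return Generator(config)


# ---------------------------------------------------------------------------
# Discriminators
# ---------------------------------------------------------------------------


class _DiscriminatorBase(Module):
    spec: DiscriminatorSpec

    def _check_input(self, x: Tensor) -> Tensor:
        if x.ndim != 2:
            raise ShapeError(f"discriminator input must be (batch, length), got {x.shape}")
        if x.shape[1] != self.spec.input_length:
            raise ShapeError(
                f"sequence length {x.shape[1]} does not match spec "
                f"input_length {self.spec.input_length}"
            )
        return x


class CNNDiscriminator(_DiscriminatorBase):
    """1-D CNN discriminator: conv/pool pairs -> FC -> 2-way softmax.

    The per-window convolution value is f(w . x_{l:r} + b) with f a leaky
    ReLU; pooling takes the max over each window.  Returns the softmax
    probability pair per sequence.
    """

    def __init__(self, spec: DiscriminatorSpec, seed: int = 0):
        super().__init__()
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.conv_params = []
        in_channels = 1
        for idx, layer in enumerate(spec.layers):
            if isinstance(layer, ConvLayerSpec):
                fan = in_channels * layer.filter_length
                bound = 1.0 / np.sqrt(fan)
                W = self.param(
                    f"conv{idx}.W",
                    rng.uniform(
                        -bound,
                        bound,
                        size=(layer.n_filters, in_channels, layer.filter_length),
                    ),
                )
                b = self.param(
                    f"conv{idx}.b",
                    rng.uniform(-bound, bound, size=(layer.n_filters,)),
                )
                self.conv_params.append((W, b))
                in_channels = layer.n_filters
        self.fc = self.add_module("fc", Dense(spec.flat_features(), spec.fc_units, rng))
        self.out = self.add_module("out", Dense(spec.fc_units, 2, rng))

    def __call__(self, x) -> Tensor:
        x = self._check_input(tensor(x))
        batch = x.shape[0]
        h = x.reshape(batch, 1, self.spec.input_length)
        conv_i = 0
        for layer in self.spec.layers:
            if isinstance(layer, ConvLayerSpec):
                if layer.zero_padding:
                    pad = Tensor(
                        np.zeros((batch, h.shape[1], layer.zero_padding))
                    )
                    h = concatenate([pad, h, pad], axis=2)
                W, b = self.conv_params[conv_i]
                conv_i += 1
                h = conv1d(h, W, b, layer.stride).leaky_relu(self.spec.leaky_slope)
            else:
                h = maxpool1d(h, layer.window, layer.stride)
        flat = h.reshape(batch, self.spec.flat_features())
        hidden = self.fc(flat).leaky_relu(self.spec.leaky_slope)
        return softmax(self.out(hidden), axis=1)


class MLPDiscriminator(_DiscriminatorBase):
    """Two-hidden-layer perceptron discriminator over the flattened sequence."""

    def __init__(self, spec: DiscriminatorSpec, seed: int = 0):
        super().__init__()
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(seed)
        widths = [spec.input_length, *spec.hidden_sizes]
        self.hidden_layers = [
            self.add_module(f"dense{i}", Dense(a, b, rng))
            for i, (a, b) in enumerate(zip(widths[:-1], widths[1:]))
        ]
        self.out = self.add_module("out", Dense(widths[-1], 2, rng))

    def __call__(self, x) -> Tensor:
        h = self._check_input(tensor(x))
        for layer in self.hidden_layers:
            h = layer(h).leaky_relu(self.spec.leaky_slope)
        return softmax(self.out(h), axis=1)


class RecurrentDiscriminator(_DiscriminatorBase):
    """Single-layer LSTM or GRU discriminator; the last hidden state feeds
    a 2-way softmax."""

    def __init__(self, spec: DiscriminatorSpec, seed: int = 0):
        super().__init__()
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(seed)
        width = spec.hidden_sizes[0]
        cell_cls = LSTM if spec.kind == "lstm" else GRU
        self.cell = self.add_module("cell", cell_cls(1, width, rng))
        self.out = self.add_module("out", Dense(width, 2, rng))

    def __call__(self, x) -> Tensor:
        x = self._check_input(tensor(x))
        batch, T = x.shape
        h_last = self.cell.last_hidden(x.reshape(batch, T, 1))
        return softmax(self.out(h_last), axis=1)


Discriminator = Union[CNNDiscriminator, MLPDiscriminator, RecurrentDiscriminator]


def build_discriminator(spec: DiscriminatorSpec, seed: int = 0) -> Discriminator:
    spec.validate()
    if spec.kind == "cnn":
        return CNNDiscriminator(spec, seed)
    if spec.kind == "mlp":
        return MLPDiscriminator(spec, seed)
    return RecurrentDiscriminator(spec, seed)


def discriminator_forward(
    disc: Discriminator, batch, decide: bool = False
) -> np.ndarray:
    """Probability-of-real per sequence (softmax component for the "true"
    class); with decide=True, the argmax binary decision instead."""
    probs = disc(np.asarray(batch, dtype=np.float64)).data
    if decide:
        return (probs[:, 0] >= probs[:, 1]).astype(np.int64)
    return probs[:, 0]
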