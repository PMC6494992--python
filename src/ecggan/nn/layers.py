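"""Neural-network building blocks on top of the autodiff engine.

Recurrent layers run an explicit Python loop over time steps; convolution
and pooling are vectorized.  All parameters are initialized from a seeded
``numpy.random.Generator`` so whole models are reproducible bit-for-bit.
"""

from __future__ import annotations

from typing import Dict, Iterator, Tuple

import numpy as np

from .autograd import Tensor, concatenate

__all__ = [
    "Module",
    "Dense",
    "Dropout",
    "VanillaRNN",
    "LSTM",
    "GRU",
    "BiLSTMLayer",
]


class Module:
    """Base class with parameter registration and train/eval mode."""

    def __init__(self) -> None:
        self._params: Dict[str, Tensor] = {}
        self._children: Dict[str, "Module"] = {}
        self.training = True

    def param(self, name: str, array: np.ndarray) -> Tensor:
        t = Tensor(array, requires_grad=True)
        self._params[name] = t
        return t

    def add_module(self, name: str, module: "Module") -> "Module":
        self._children[name] = module
        return module

    def named_parameters(self, prefix: str = "") -> Iterator[Tuple[str, Tensor]]:
        for name, t in self._params.items():
            yield prefix + name, t
        for cname, child in self._children.items():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self) -> Iterator[Tensor]:
        for _, t in self.named_parameters():
            yield t

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for child in self._children.values():
            child.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {name: t.data.copy() for name, t in self.named_parameters()}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(
                f"state dict mismatch: missing {sorted(missing)}, "
                f"unexpected {sorted(extra)}"
            )
        for name, t in own.items():
            value = np.asarray(state[name], dtype=np.float64)
            if value.shape != t.data.shape:
                raise ValueError(
                    f"shape mismatch for {name}: "
                    f"{value.shape} vs {t.data.shape}"
                )
            t.data = value.copy()


def _uniform_init(
    rng: np.random.Generator, shape: Tuple[int, ...], fan_in: int
) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Dense(Module):
    """Affine map ``x @ W + b`` applied over the last axis."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.W = self.param("W", _uniform_init(rng, (in_features, out_features), in_features))
        self.b = self.param("b", _uniform_init(rng, (out_features,), in_features))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class Dropout(Module):
    """Inverted dropout; identity in eval mode.

    Draws masks from its own seeded generator so a model's forward passes
    are reproducible given the seed and call order.
    """

    def __init__(self, p: float, seed: int = 0):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p
        self._rng = np.random.default_rng(seed)

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (self._rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class _Recurrent(Module):
    """Shared driver: run a cell over (batch, T, features), return (batch, T, hidden)."""

    hidden_units: int

    def _init_state(self, batch: int):
        raise NotImplementedError

    def _step(self, xt: Tensor, state):
        raise NotImplementedError

    def __call__(self, x: Tensor, reverse: bool = False) -> Tensor:
        batch, T, _ = x.shape
        state = self._init_state(batch)
        outputs: list = [None] * T
        steps = range(T - 1, -1, -1) if reverse else range(T)
        for t in steps:
            h, state = self._step(x[:, t, :], state)
            outputs[t] = h.reshape(batch, 1, self.hidden_units)
        return concatenate(outputs, axis=1)

    def last_hidden(self, x: Tensor) -> Tensor:
        """Final hidden state after a forward pass over the sequence."""
        batch, T, _ = x.shape
        state = self._init_state(batch)
        h = None
        for t in range(T):
            h, state = self._step(x[:, t, :], state)
        return h


class VanillaRNN(_Recurrent):
    """Single tanh recurrence: h_t = tanh([x_t, h_{t-1}] @ W + b)."""

    def __init__(self, in_features: int, hidden_units: int, rng: np.random.Generator):
        super().__init__()
        self.in_features = in_features
        self.hidden_units = hidden_units
        fan = in_features + hidden_units
        self.W = self.param("W", _uniform_init(rng, (fan, hidden_units), fan))
        self.b = self.param("b", _uniform_init(rng, (hidden_units,), fan))

    def _init_state(self, batch: int):
        return Tensor(np.zeros((batch, self.hidden_units)))

    def _step(self, xt: Tensor, h: Tensor):
        h_new = (concatenate([xt, h], axis=1) @ self.W + self.b).tanh()
        return h_new, h_new


class LSTM(_Recurrent):
    """Standard LSTM; gates computed from one fused affine map.

    Initial hidden and cell states are zero vectors.
    """

    def __init__(self, in_features: int, hidden_units: int, rng: np.random.Generator):
        super().__init__()
        self.in_features = in_features
        self.hidden_units = hidden_units
        fan = in_features + hidden_units
        self.W = self.param("W", _uniform_init(rng, (fan, 4 * hidden_units), fan))
        self.b = self.param("b", _uniform_init(rng, (4 * hidden_units,), fan))

    def _init_state(self, batch: int):
        zeros = np.zeros((batch, self.hidden_units))
        return Tensor(zeros), Tensor(zeros.copy())

    def _step(self, xt: Tensor, state):
        h_prev, c_prev = state
        z = concatenate([xt, h_prev], axis=1) @ self.W + self.b
        n = self.hidden_units
        i = z[:, 0 * n : 1 * n].sigmoid()
        f = z[:, 1 * n : 2 * n].sigmoid()
        g = z[:, 2 * n : 3 * n].tanh()
        o = z[:, 3 * n : 4 * n].sigmoid()
        c = f * c_prev + i * g
        h = o * c.tanh()
        return h, (h, c)


class GRU(_Recurrent):
    """Gated recurrent unit with update gate z and reset gate r."""

    def __init__(self, in_features: int, hidden_units: int, rng: np.random.Generator):
        super().__init__()
        self.in_features = in_features
        self.hidden_units = hidden_units
        fan = in_features + hidden_units
        self.W_zr = self.param("W_zr", _uniform_init(rng, (fan, 2 * hidden_units), fan))
        self.b_zr = self.param("b_zr", _uniform_init(rng, (2 * hidden_units,), fan))
        self.W_h = self.param("W_h", _uniform_init(rng, (fan, hidden_units), fan))
        self.b_h = self.param("b_h", _uniform_init(rng, (hidden_units,), fan))

    def _init_state(self, batch: int):
        return Tensor(np.zeros((batch, self.hidden_units)))

    def _step(self, xt: Tensor, h_prev: Tensor):
        n = self.hidden_units
        zr = concatenate([xt, h_prev], axis=1) @ self.W_zr + self.b_zr
        z = zr[:, :n].sigmoid()
        r = zr[:, n:].sigmoid()
        h_tilde = (concatenate([xt, r * h_prev], axis=1) @ self.W_h + self.b_h).tanh()
        h = (1.0 - z) * h_prev + z * h_tilde
        return h, h


class BiLSTMLayer(Module):
    """One bidirectional LSTM layer.

    A forward and a backward LSTM each produce per-step hidden states; the
    layer output at each step is a tanh of an affine combination of the two
    directions' states, of width ``2 * hidden_units`` (so the combined state
    width for 100 cells per direction is 200).
    """

    def __init__(self, in_features: int, hidden_units: int, rng: np.random.Generator):
        super().__init__()
        self.in_features = in_features
        self.hidden_units = hidden_units
        self.out_features = 2 * hidden_units
        self.fwd = self.add_module("fwd", LSTM(in_features, hidden_units, rng))
        self.bwd = self.add_module("bwd", LSTM(in_features, hidden_units, rng))
        self.W_f = self.param(
            "W_f", _uniform_init(rng, (hidden_units, self.out_features), 2 * hidden_units)
        )
        self.W_b = self.param(
            "W_b", _uniform_init(rng, (hidden_units, self.out_features), 2 * hidden_units)
        )
        self.b_o = self.param(
            "b_o", _uniform_init(rng, (self.out_features,), 2 * hidden_units)
        )

    def __call__(self, x: Tensor) -> Tensor:
        h_fwd = self.fwd(x)
        h_bwd = self.bwd(x, reverse=True)
        return (h_fwd @ self.W_f + h_bwd @ self.W_b + self.b_o).tanh()
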