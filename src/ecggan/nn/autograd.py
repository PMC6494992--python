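"""Reverse-mode automatic differentiation over NumPy arrays.

A small tape-based engine in the spirit of micrograd, generalized to
ndarray-valued nodes with broadcasting.  It exists so the recurrent and
convolutional networks in this package can be trained with plain NumPy:
every differentiable operation builds a node holding its inputs and a
closure that accumulates gradients into them.

Only the operations the package's models need are provided; each op's
backward pass is hand-derived and unit-tested against finite differences.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "concatenate",
    "conv1d",
    "maxpool1d",
    "softmax",
]


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over broadcast axes so it matches `shape`."""
    if grad.shape == shape:
        return grad
    # Sum over leading axes added by broadcasting.
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # Sum over axes that were size-1 in the original.
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: Sequence["Tensor"] = (),
        _backward: Optional[Callable[[np.ndarray], None]] = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in _parents
        )
        self._parents = tuple(_parents)
        self._backward = _backward

    # -- bookkeeping ------------------------------------------------------

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        """Backpropagate from this node through the whole tape."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        # Topological order by DFS.
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = tensor(other)
        out_data = self.data + other.data

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor(out_data, _parents=(self, other), _backward=backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor(-self.data, _parents=(self,), _backward=backward)

    def __sub__(self, other) -> "Tensor":
        return self + (-tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = tensor(other)
        out_data = self.data * other.data

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor(out_data, _parents=(self, other), _backward=backward)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        return self * tensor(other) ** -1.0

    def __rtruediv__(self, other) -> "Tensor":
        return tensor(other) * self ** -1.0

    def __pow__(self, exponent: float) -> "Tensor":
        out_data = self.data ** exponent

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1))

        return Tensor(out_data, _parents=(self,), _backward=backward)

    def __matmul__(self, other) -> "Tensor":
        other = tensor(other)
        out_data = self.data @ other.data

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.shape))

        return Tensor(out_data, _parents=(self, other), _backward=backward)

    # -- elementwise nonlinearities ---------------------------------------

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * out_data)

        return Tensor(out_data, _parents=(self,), _backward=backward)

    def log(self) -> "Tensor":
        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g / self.data)

        return Tensor(np.log(self.data), _parents=(self,), _backward=backward)

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * (1.0 - out_data ** 2))

        return Tensor(out_data, _parents=(self,), _backward=backward)

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor(out_data, _parents=(self,), _backward=backward)

    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        factor = np.where(self.data > 0, 1.0, slope)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * factor)

        return Tensor(self.data * factor, _parents=(self,), _backward=backward)

    # -- reductions and reshaping -----------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g: np.ndarray) -> None:
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        return Tensor(out_data, _parents=(self,), _backward=backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old_shape = self.shape

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g.reshape(old_shape))

        return Tensor(
            self.data.reshape(shape), _parents=(self,), _backward=backward
        )

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inverse = tuple(np.argsort(axes))

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g.transpose(inverse))

        return Tensor(
            self.data.transpose(axes), _parents=(self,), _backward=backward
        )

    def __getitem__(self, key) -> "Tensor":
        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, key, g)
                self._accumulate(full)

        return Tensor(self.data[key], _parents=(self,), _backward=backward)


def tensor(value, requires_grad: bool = False) -> Tensor:
    """Coerce `value` to a Tensor (no-op if it already is one)."""
    if isinstance(value, Tensor):
        return value
    return Tensor(value, requires_grad=requires_grad)


def concatenate(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g: np.ndarray) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return Tensor(out_data, _parents=tuple(tensors), _backward=backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax with an analytic Jacobian-vector product."""
    x = tensor(x)
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            inner = (g * s).sum(axis=axis, keepdims=True)
            x._accumulate(s * (g - inner))

    return Tensor(s, _parents=(x,), _backward=backward)


def _window_indices(length: int, window: int, stride: int) -> np.ndarray:
    """(n_windows, window) gather indices for a 1-D sliding window."""
    n_out = (length - window) // stride + 1
    starts = np.arange(n_out) * stride
    return starts[:, None] + np.arange(window)[None, :]


def conv1d(x: Tensor, weight: Tensor, bias: Tensor, stride: int) -> Tensor:
    """1-D cross-correlation.

    x: (batch, in_channels, length); weight: (out_channels, in_channels,
    filter_length); bias: (out_channels,).  Valid padding; zero padding, if
    wanted, is applied by the caller before this op.
    """
    x, weight, bias = tensor(x), tensor(weight), tensor(bias)
    batch, c_in, length = x.shape
    c_out, c_in_w, h = weight.shape
    if c_in_w != c_in:
        raise ValueError(f"channel mismatch: input {c_in}, weight {c_in_w}")
    if length < h:
        raise ValueError(f"input length {length} shorter than filter {h}")
    idx = _window_indices(length, h, stride)
    cols = x.data[:, :, idx]  # (batch, c_in, n_out, h)
    out_data = (
        np.einsum("bcoh,mch->bmo", cols, weight.data)
        + bias.data[None, :, None]
    )

    def backward(g: np.ndarray) -> None:
        if weight.requires_grad:
            weight._accumulate(np.einsum("bmo,bcoh->mch", g, cols))
        if bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2)))
        if x.requires_grad:
            gcols = np.einsum("bmo,mch->bcoh", g, weight.data)
            gx = np.zeros_like(x.data)
            np.add.at(
                gx.transpose(2, 0, 1),
                idx.ravel(),
                gcols.transpose(2, 3, 0, 1).reshape(-1, batch, c_in),
            )
            x._accumulate(gx)

    return Tensor(out_data, _parents=(x, weight, bias), _backward=backward)


def maxpool1d(x: Tensor, window: int, stride: int) -> Tensor:
    """1-D max pooling over the last axis of a (batch, channels, length) input."""
    x = tensor(x)
    batch, channels, length = x.shape
    if length < window:
        raise ValueError(f"input length {length} shorter than window {window}")
    idx = _window_indices(length, window, stride)
    cols = x.data[:, :, idx]  # (batch, channels, n_out, window)
    argmax = cols.argmax(axis=-1)  # (batch, channels, n_out)
    out_data = np.take_along_axis(cols, argmax[..., None], axis=-1)[..., 0]

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            src = idx[np.arange(idx.shape[0])[None, None, :], argmax]
            b_idx = np.arange(batch)[:, None, None]
            c_idx = np.arange(channels)[None, :, None]
            np.add.at(gx, (b_idx, c_idx, src), g)
            x._accumulate(gx)

    return Tensor(out_data, _parents=(x,), _backward=backward)
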