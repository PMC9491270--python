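"""Reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for small text classifiers: broadcast-aware
elementwise arithmetic, matmul, slicing/concat, the nonlinearities, an
embedding gather, a 1-D convolution (im2col), max-over-time pooling and the
two classification losses.  Graphs are built eagerly per forward pass and
freed after ``backward``.
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional, Sequence

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        parents: tuple["Tensor", ...] = (),
        backward: Optional[Callable[[np.ndarray], None]] = None,
        dtype=None,
    ):
        arr = np.asarray(data) if dtype is None else np.asarray(data, dtype=dtype)
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float32)
        self.data = arr
        self.grad: Optional[np.ndarray] = None
        self._parents = parents
        self._backward = backward

    # -- graph -------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() is only defined for scalar losses")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        if isinstance(other, Tensor):
            out_data = self.data + other.data

            def bw(g):
                self._accumulate(_unbroadcast(g, self.data.shape))
                other._accumulate(_unbroadcast(g, other.data.shape))

            return Tensor(out_data, (self, other), bw)
        out_data = self.data + other

        def bw(g):
            self._accumulate(_unbroadcast(g, self.data.shape))

        return Tensor(out_data, (self,), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accumulate(-g)

        return Tensor(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-other if isinstance(other, Tensor) else -np.asarray(other))

    def __mul__(self, other):
        if isinstance(other, Tensor):
            out_data = self.data * other.data

            def bw(g):
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

            return Tensor(out_data, (self, other), bw)
        const = np.asarray(other, dtype=self.data.dtype)

        def bw(g):
            self._accumulate(_unbroadcast(g * const, self.data.shape))

        return Tensor(self.data * const, (self,), bw)

    __rmul__ = __mul__

    def __matmul__(self, other: "Tensor"):
        out_data = self.data @ other.data

        def bw(g):
            self._accumulate(g @ other.data.T)
            other._accumulate(self.data.T @ g)

        return Tensor(out_data, (self, other), bw)

    def __getitem__(self, key):
        def bw(g):
            full = np.zeros_like(self.data)
            full[key] = g
            self._accumulate(full)

        return Tensor(self.data[key], (self,), bw)

    def reshape(self, *shape):
        orig = self.data.shape

        def bw(g):
            self._accumulate(g.reshape(orig))

        return Tensor(self.data.reshape(*shape), (self,), bw)

    # -- reductions & nonlinearities --------------------------------------
    def sum(self):
        def bw(g):
            self._accumulate(np.full_like(self.data, g))

        return Tensor(self.data.sum(), (self,), bw)

    def mean(self):
        n = self.data.size

        def bw(g):
            self._accumulate(np.full_like(self.data, g / n))

        return Tensor(self.data.mean(), (self,), bw)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            self._accumulate(g * s * (1.0 - s))

        return Tensor(s, (self,), bw)

    def tanh(self):
        t = np.tanh(self.data)

        def bw(g):
            self._accumulate(g * (1.0 - t * t))

        return Tensor(t, (self,), bw)

    def relu(self):
        mask = self.data > 0

        def bw(g):
            self._accumulate(g * mask)

        return Tensor(self.data * mask, (self,), bw)


# -- composite ops ---------------------------------------------------------

def embedding(weight: Tensor, indices: np.ndarray) -> Tensor:
    """Row gather ``weight[indices]`` with scatter-add backward."""
    idx = np.asarray(indices)

    def bw(g):
        full = np.zeros_like(weight.data)
        np.add.at(full, idx, g)
        weight._accumulate(full)

    return Tensor(weight.data[idx], (weight,), bw)


def conv1d(x: Tensor, weight: Tensor, bias: Tensor, kernel_size: int) -> Tensor:
    """Valid 1-D convolution over time.

    x: (B, L, D); weight: (kernel_size * D, F); bias: (F,). Returns
    (B, L - kernel_size + 1, F).
    """
    B, L, D = x.data.shape
    K = kernel_size
    T = L - K + 1
    if T < 1:
        raise ValueError(f"sequence length {L} shorter than kernel size {K}")
    # (B, T, D, K) -> (B, T, K, D) -> (B*T, K*D)
    wins = np.lib.stride_tricks.sliding_window_view(x.data, K, axis=1)
    cols = np.ascontiguousarray(wins.transpose(0, 1, 3, 2)).reshape(B * T, K * D)
    out = (cols @ weight.data + bias.data).reshape(B, T, -1)

    def bw(g):
        g2 = g.reshape(B * T, -1)
        weight._accumulate(cols.T @ g2)
        bias._accumulate(g2.sum(axis=0))
        dcols = (g2 @ weight.data.T).reshape(B, T, K, D)
        dx = np.zeros_like(x.data)
        for k in range(K):
            dx[:, k : k + T, :] += dcols[:, :, k, :]
        x._accumulate(dx)

    return Tensor(out, (x, weight, bias), bw)


def max_over_axis(x: Tensor, axis: int = 1) -> Tensor:
    """Max pooling along one axis (gradient flows to the argmax only)."""
    am = np.expand_dims(x.data.argmax(axis=axis), axis)
    out = np.take_along_axis(x.data, am, axis=axis).squeeze(axis)

    def bw(g):
        full = np.zeros_like(x.data)
        np.put_along_axis(full, am, np.expand_dims(g, axis), axis=axis)
        x._accumulate(full)

    return Tensor(out, (x,), bw)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    return Tensor(out, tuple(tensors), bw)


def dropout(x: Tensor, rate: float, rng: np.random.Generator, train: bool) -> Tensor:
    """Inverted dropout; identity when evaluating or rate == 0."""
    if not train or rate <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= rate) / (1.0 - rate)
    return x * mask.astype(x.data.dtype)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on raw logits (numerically stable form)."""
    z = logits.data.reshape(-1)
    t = np.asarray(targets, dtype=z.dtype).reshape(-1)
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    p = 1.0 / (1.0 + np.exp(-z))
    n = len(z)

    def bw(g):
        logits._accumulate((g * (p - t) / n).reshape(logits.data.shape))

    return Tensor(loss.mean(), (logits,), bw)


def softmax_cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean cross-entropy for (B, C) logits and integer class targets."""
    z = logits.data
    z = z - z.max(axis=1, keepdims=True)
    expz = np.exp(z)
    probs = expz / expz.sum(axis=1, keepdims=True)
    t = np.asarray(targets, dtype=np.int64)
    n = len(t)
    loss = -np.log(np.clip(probs[np.arange(n), t], 1e-12, None)).mean()

    def bw(g):
        d = probs.copy()
        d[np.arange(n), t] -= 1.0
        logits._accumulate(g * d / n)

    return Tensor(loss, (logits,), bw)
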