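"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Just enough machinery for the models in this package: broadcasting
elementwise arithmetic, matmul, tanh/sigmoid, concatenation, static
slicing, embedding-row gather, sliding-window unfold (for text
convolution), max-over-axis, means, and a fused softmax cross-entropy.
All computation is float64; gradients are checked against central finite
differences in the test suite.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

Array = np.ndarray


def _as_data(x) -> Array:
    return np.asarray(x, dtype=np.float64)


class Tensor:
    """A node in the computation graph: value, grad, and backward rule."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data: Array = _as_data(data)
        self.grad: Array | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[Array], Iterable[Array | None]] | None = None

    # -- graph construction -------------------------------------------------
    @staticmethod
    def _make(data: Array, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- backward pass ------------------------------------------------------
    def backward(self, grad: Array | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can exceed the recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        grads: dict[int, Array] = {id(self): _as_data(grad)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None or not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg

    # -- operators ----------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


# ---------------------------------------------------------------- primitives


def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data + b.data
    return Tensor._make(
        out, (a, b), lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape))
    )


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data * b.data
    return Tensor._make(
        out,
        (a, b),
        lambda g: (
            _unbroadcast(g * b.data, a.shape),
            _unbroadcast(g * a.data, b.shape),
        ),
    )


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = np.matmul(a.data, b.data)

    def backward(g: Array):
        ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
        gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
        if a.data.ndim == 1:  # vector @ matrix
            ga = np.matmul(g, b.data.T) if b.data.ndim == 2 else ga
        return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

    return Tensor._make(out, (a, b), backward)


def tanh(x) -> Tensor:
    x = as_tensor(x)
    out = np.tanh(x.data)
    return Tensor._make(out, (x,), lambda g: (g * (1.0 - out * out),))


def sigmoid(x) -> Tensor:
    x = as_tensor(x)
    out = 1.0 / (1.0 + np.exp(-x.data))
    return Tensor._make(out, (x,), lambda g: (g * out * (1.0 - out),))


def concat(parts: Sequence[Tensor], axis: int = -1) -> Tensor:
    parts = [as_tensor(p) for p in parts]
    out = np.concatenate([p.data for p in parts], axis=axis)
    sizes = [p.data.shape[axis] for p in parts]
    splits = np.cumsum(sizes)[:-1]

    def backward(g: Array):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(out, parts, backward)


def narrow(x: Tensor, axis: int, start: int, length: int) -> Tensor:
    """Static slice of `length` elements from `start` along `axis`."""
    x = as_tensor(x)
    index = [slice(None)] * x.ndim
    index[axis] = slice(start, start + length)
    index = tuple(index)
    out = x.data[index]

    def backward(g: Array):
        gx = np.zeros_like(x.data)
        gx[index] = g
        return (gx,)

    return Tensor._make(out, (x,), backward)


def gather_rows(weight: Tensor, idx: Array) -> Tensor:
    """Embedding lookup: rows of `weight` at integer array `idx`."""
    weight = as_tensor(weight)
    idx = np.asarray(idx, dtype=np.intp)
    out = weight.data[idx]

    def backward(g: Array):
        gw = np.zeros_like(weight.data)
        np.add.at(gw, idx.reshape(-1), g.reshape(-1, weight.data.shape[1]))
        return (gw,)

    return Tensor._make(out, (weight,), backward)


def unfold_windows(x: Tensor, width: int) -> Tensor:
    """Sliding windows over the time axis of a (B, N, d) tensor.

    Returns (B, N - width + 1, width * d): each position's window of
    `width` consecutive token embeddings, flattened — the input a text
    convolution filter bank contracts against.
    """
    x = as_tensor(x)
    B, N, d = x.data.shape
    if N < width:
        raise ValueError(f"sequence length {N} shorter than window width {width}")
    P = N - width + 1
    out = np.empty((B, P, width * d))
    for i in range(P):
        out[:, i, :] = x.data[:, i : i + width, :].reshape(B, width * d)

    def backward(g: Array):
        gx = np.zeros_like(x.data)
        for i in range(P):
            gx[:, i : i + width, :] += g[:, i, :].reshape(B, width, d)
        return (gx,)

    return Tensor._make(out, (x,), backward)


def max_along(x: Tensor, axis: int) -> Tensor:
    """Maximum along `axis`; gradient splits equally among ties."""
    x = as_tensor(x)
    out = x.data.max(axis=axis)

    def backward(g: Array):
        mask = x.data == np.expand_dims(out, axis)
        counts = mask.sum(axis=axis, keepdims=True)
        return (mask / counts * np.expand_dims(g, axis),)

    return Tensor._make(out, (x,), backward)


def reshape(x: Tensor, shape: tuple[int, ...]) -> Tensor:
    x = as_tensor(x)
    out = x.data.reshape(shape)
    return Tensor._make(out, (x,), lambda g: (g.reshape(x.shape),))


def mean(x: Tensor) -> Tensor:
    x = as_tensor(x)
    n = x.data.size
    out = np.asarray(x.data.mean())
    return Tensor._make(out, (x,), lambda g: (np.broadcast_to(g / n, x.shape).copy(),))


def softmax(logits: Array, axis: int = -1) -> Array:
    """Plain-array softmax for inference-time probabilities."""
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(
    logits: Tensor, targets: Array, mask: Array | None = None
) -> Tensor:
    """Mean cross-entropy of integer `targets` under `logits` (..., C).

    `mask` (same shape as `targets`, 0/1) excludes positions — used to
    ignore padding when averaging token-level losses. Returns a scalar.
    """
    logits = as_tensor(logits)
    targets = np.asarray(targets, dtype=np.intp)
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=-1))
    tgt_logit = np.take_along_axis(z, targets[..., None], axis=-1)[..., 0]
    losses = lse - tgt_logit
    if mask is None:
        m = np.ones_like(losses)
    else:
        m = np.asarray(mask, dtype=np.float64)
    count = m.sum()
    if count == 0:
        raise ValueError("softmax_cross_entropy: empty mask")
    out = np.asarray((losses * m).sum() / count)

    def backward(g: Array):
        p = np.exp(z) / np.exp(z).sum(axis=-1, keepdims=True)
        onehot = np.zeros_like(p)
        np.put_along_axis(onehot, targets[..., None], 1.0, axis=-1)
        return (g * (p - onehot) * m[..., None] / count,)

    return Tensor._make(out, (logits,), backward)
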