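"""Neural layers built on the autograd core: Linear, Embedding, LSTM cell."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: recursively collects parameters from attributes."""

    def parameters(self) -> Iterator[Parameter]:
        seen: set[int] = set()
        for obj in self.__dict__.values():
            yield from _params_of(obj, seen)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name → array mapping of all parameters, for checkpoints."""
        out: dict[str, np.ndarray] = {}
        for i, p in enumerate(self.parameters()):
            out[f"p{i:03d}"] = p.data
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            a = arrays[f"p{i:03d}"]
            if a.shape != p.data.shape:
                raise ValueError(
                    f"checkpoint shape mismatch at p{i:03d}: "
                    f"{a.shape} vs {p.data.shape}"
                )
            p.data = np.array(a, dtype=np.float64)

    def copy_weights(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def restore_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.parameters(), weights):
            p.data = w.copy()


def _params_of(obj, seen: set[int]):
    if isinstance(obj, Parameter):
        if id(obj) not in seen:
            seen.add(id(obj))
            yield obj
    elif isinstance(obj, Module):
        for p in obj.parameters():
            if id(p) not in seen:
                seen.add(id(p))
                yield p
    elif isinstance(obj, (list, tuple)):
        for item in obj:
            yield from _params_of(item, seen)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, scale: float | None = None):
        if scale is None:
            scale = float(np.sqrt(6.0 / (n_in + n_out)))  # Glorot uniform
        self.weight = Parameter(rng.uniform(-scale, scale, size=(n_in, n_out)))
        self.bias = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return ag.add(ag.matmul(x, self.weight), self.bias)


class Embedding(Module):
    """Token-index → vector lookup with an always-zero padding row."""

    def __init__(self, weight: np.ndarray, pad_index: int = 0):
        self.weight = Parameter(np.array(weight, dtype=np.float64))
        self.pad_index = pad_index
        self.weight.data[pad_index] = 0.0

    def __call__(self, idx: np.ndarray) -> Tensor:
        return ag.gather_rows(self.weight, idx)

    def mask_pad_grad(self) -> None:
        """Zero the padding row's gradient so PAD stays the zero vector."""
        if self.weight.grad is not None:
            self.weight.grad[self.pad_index] = 0.0


class LSTMCell(Module):
    """Standard LSTM cell; gate order [input, forget, cell, output].

    The forget-gate bias starts at 1 so memory persists early in training.
    """

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        scale = float(np.sqrt(6.0 / (n_in + hidden + 4 * hidden)))
        self.w_x = Parameter(rng.uniform(-scale, scale, size=(n_in, 4 * hidden)))
        self.w_h = Parameter(rng.uniform(-scale, scale, size=(hidden, 4 * hidden)))
        bias = np.zeros(4 * hidden)
        bias[hidden : 2 * hidden] = 1.0
        self.bias = Parameter(bias)
        self.hidden = hidden

    def step(self, x: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        k = self.hidden
        gates = ag.add(
            ag.add(ag.matmul(x, self.w_x), ag.matmul(h, self.w_h)), self.bias
        )
        i = ag.sigmoid(ag.narrow(gates, -1, 0, k))
        f = ag.sigmoid(ag.narrow(gates, -1, k, k))
        g = ag.tanh(ag.narrow(gates, -1, 2 * k, k))
        o = ag.sigmoid(ag.narrow(gates, -1, 3 * k, k))
        c_new = ag.add(ag.mul(f, c), ag.mul(i, g))
        h_new = ag.mul(o, ag.tanh(c_new))
        return h_new, c_new

    def masked_step(
        self, x: Tensor, h: Tensor, c: Tensor, mask: np.ndarray
    ) -> tuple[Tensor, Tensor]:
        """Step that freezes state on padded positions (mask 0 → carry)."""
        h_new, c_new = self.step(x, h, c)
        m = mask[:, None].astype(np.float64)
        h_out = ag.add(ag.mul(h_new, m), ag.mul(h, 1.0 - m))
        c_out = ag.add(ag.mul(c_new, m), ag.mul(c, 1.0 - m))
        return h_out, c_out


def dropout(x: Tensor, rate: float, rng: np.random.Generator | None) -> Tensor:
    """Inverted dropout; identity when rate is 0 or rng is None (inference)."""
    if rate <= 0.0 or rng is None:
        return x
    keep = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return ag.mul(x, keep)
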