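"""Stochastic gradient descent with optional gradient-norm clipping."""

from __future__ import annotations

import math
from typing import Sequence

from .layers import Parameter


class SGD:
    def __init__(
        self,
        params: Sequence[Parameter],
        lr: float,
        clip_norm: float | None = None,
    ):
        if lr <= 0:
            raise ValueError(f"learning rate must be positive, got {lr}")
        self.params = list(params)
        self.lr = lr
        self.clip_norm = clip_norm

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        if self.clip_norm is not None:
            total = math.sqrt(
                sum(float((p.grad * p.grad).sum()) for p in self.params if p.grad is not None)
            )
            if total > self.clip_norm and total > 0:
                scale = self.clip_norm / total
                for p in self.params:
                    if p.grad is not None:
                        p.grad = p.grad * scale
        for p in self.params:
            if p.grad is not None:
                p.data = p.data - self.lr * p.grad
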