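"""Padding variable-length index sequences into rectangular batches."""

from __future__ import annotations

from typing import Sequence

import numpy as np


def pad_batch(
    sequences: Sequence[Sequence[int]], pad_index: int = 0, min_length: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Pad integer sequences to a (B, N) matrix plus a length vector.

    N is the longest sequence, floored at `min_length` (convolution needs
    at least the widest filter's window). Padding never changes model
    output: recurrences carry state through padded steps and pooled
    convolution positions beyond a sentence's own windows are masked.
    """
    if not sequences:
        raise ValueError("empty batch")
    lengths = np.array([len(s) for s in sequences], dtype=np.intp)
    if lengths.min() < 1:
        raise ValueError("batch contains an empty sequence")
    width = max(int(lengths.max()), min_length)
    out = np.full((len(sequences), width), pad_index, dtype=np.intp)
    for i, s in enumerate(sequences):
        out[i, : len(s)] = s
    return out, lengths


def iter_batches(n: int, batch_size: int, rng: np.random.Generator | None = None):
    """Yield index arrays of size <= batch_size; shuffled when rng given."""
    order = np.arange(n)
    if rng is not None:
        rng.shuffle(order)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]
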