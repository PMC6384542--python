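"""Word-embedding matrices: random initialization and pretrained vectors.

Vectors are |V| x d, one row per vocabulary entry, d = 200 by default.
Pretrained vectors load from the word2vec/GloVe whitespace text format
(token followed by d reals per line) and are fine-tuned during training
unless frozen.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from ._rng import derive_rng
from .records import ValidationError
from .vocab import Vocabulary

INIT_RANGE = 0.25  # uniform [-0.25, 0.25], conventional for CNN text models


@dataclass
class EmbeddingMatrix:
    """|V| x d embedding table; the PAD row is all-zero and stays zero."""

    vectors: np.ndarray
    source: str  # "random" | "pretrained"
    trainable: bool = True
    coverage: float | None = None  # fraction of vocab found in a pretrained file

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2:
            raise ValidationError("embedding matrix must be 2-D")


def init_embeddings(vocab: Vocabulary, dim: int = 200, seed: int = 0) -> EmbeddingMatrix:
    """Random embeddings, i.i.d. uniform on [-0.25, 0.25]; PAD row zero."""
    if dim < 1:
        raise ValidationError(f"embedding dim must be >= 1, got {dim}")
    rng = derive_rng(seed, "init_embeddings")
    vectors = rng.uniform(-INIT_RANGE, INIT_RANGE, size=(len(vocab), dim))
    vectors[vocab.pad_index] = 0.0
    return EmbeddingMatrix(vectors=vectors, source="random")


class EmbeddingFormatError(ValueError):
    """A pretrained-vector file line could not be parsed."""


def load_pretrained(
    path: str | Path, vocab: Vocabulary, dim: int = 200, seed: int = 0
) -> EmbeddingMatrix:
    """Load GloVe/word2vec text vectors for the vocabulary.

    In-vocabulary tokens take their file vectors; tokens absent from the
    file fall back to the seeded random initialization. A word2vec-style
    count header line is skipped if present. Records the coverage
    fraction (loaded / |V|, specials excluded).
    """
    path = Path(path)
    base = init_embeddings(vocab, dim=dim, seed=seed)
    vectors = base.vectors
    n_loaded = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            parts = raw.rstrip("\n").split()
            if not parts:
                continue
            if lineno == 1 and len(parts) == 2 and all(p.isdigit() for p in parts):
                continue  # word2vec header: "<count> <dim>"
            token, values = parts[0], parts[1:]
            if len(values) != dim:
                raise EmbeddingFormatError(
                    f"{path}:{lineno}: expected {dim} values, got {len(values)}"
                )
            if token not in vocab:
                continue
            try:
                vec = np.array([float(v) for v in values])
            except ValueError as exc:
                raise EmbeddingFormatError(f"{path}:{lineno}: {exc}") from exc
            vectors[vocab.index(token)] = vec
            n_loaded += 1
    vectors[vocab.pad_index] = 0.0
    n_content = len(vocab) - 4
    coverage = n_loaded / n_content if n_content else 0.0
    return EmbeddingMatrix(
        vectors=vectors, source="pretrained", coverage=coverage
    )


def save_glove_text(
    path: str | Path, tokens: Sequence[str], vectors: np.ndarray, fmt: str = "%.6f"
) -> None:
    """Write vectors in GloVe text format (one token + d reals per line)."""
    vectors = np.asarray(vectors)
    if len(tokens) != vectors.shape[0]:
        raise ValidationError("token count does not match vector rows")
    with Path(path).open("w") as fh:
        for tok, row in zip(tokens, vectors):
            fh.write(tok + " " + " ".join(fmt % v for v in row) + "\n")
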