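"""Vocabulary: token ↔ index bijection with reserved special tokens.

PAD (index 0) pads batches and its embedding row is pinned to zero;
UNK absorbs out-of-vocabulary tokens; BOS/EOS delimit the decoder's
target sequence in the sequence autoencoder and are stripped for the
convolutional path.
"""

from __future__ import annotations

import hashlib
import json
from collections import Counter
from pathlib import Path
from typing import Iterable, Sequence

from .records import SentenceRecord, ValidationError

PAD, UNK, BOS, EOS = "<pad>", "<unk>", "<bos>", "<eos>"
SPECIALS = (PAD, UNK, BOS, EOS)


class Vocabulary:
    """Immutable token↔index bijection; specials occupy indices 0–3."""

    def __init__(self, tokens: Sequence[str]):
        for s in SPECIALS:
            if s in tokens:
                raise ValidationError(f"special token {s!r} present in token list")
        self._index_to_token: list[str] = list(SPECIALS) + list(tokens)
        self._token_to_index = {t: i for i, t in enumerate(self._index_to_token)}
        if len(self._token_to_index) != len(self._index_to_token):
            raise ValidationError("duplicate token in vocabulary")

    def __len__(self) -> int:
        return len(self._index_to_token)

    def __contains__(self, token: str) -> bool:
        return token in self._token_to_index

    @property
    def pad_index(self) -> int:
        return 0

    @property
    def unk_index(self) -> int:
        return 1

    @property
    def bos_index(self) -> int:
        return 2

    @property
    def eos_index(self) -> int:
        return 3

    def index(self, token: str) -> int:
        return self._token_to_index.get(token, self.unk_index)

    def token(self, index: int) -> str:
        return self._index_to_token[index]

    @property
    def tokens(self) -> list[str]:
        return list(self._index_to_token)

    def encode(self, tokens: Iterable[str]) -> list[int]:
        return [self.index(t) for t in tokens]

    def decode(self, indices: Iterable[int]) -> list[str]:
        return [self.token(i) for i in indices]

    def content_hash(self) -> str:
        """Stable digest used to detect checkpoint/vocabulary mismatches."""
        h = hashlib.sha256("\n".join(self._index_to_token).encode("utf-8"))
        return h.hexdigest()[:16]

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self._index_to_token))

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        tokens = json.loads(Path(path).read_text())
        if list(tokens[:4]) != list(SPECIALS):
            raise ValidationError(f"{path}: not a vocabulary file (bad specials)")
        return cls(tokens[4:])


def build_vocab(records: Sequence[SentenceRecord], min_freq: int = 1) -> Vocabulary:
    """Index tokens with frequency >= min_freq.

    Ordering is descending frequency with lexicographic tie-break, after
    the four reserved specials. Everything rarer maps to UNK.
    """
    if not records:
        raise ValidationError("cannot build a vocabulary from an empty corpus")
    counts: Counter[str] = Counter()
    for r in records:
        counts.update(r.tokens)
    kept = [t for t, c in counts.items() if c >= min_freq]
    kept.sort(key=lambda t: (-counts[t], t))
    return Vocabulary(kept)
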