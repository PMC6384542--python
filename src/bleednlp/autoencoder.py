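"""Bidirectional LSTM sequence autoencoder.

The encoder scans the sentence forward and backward; by default both
directions share one set of LSTM weights (a single LSTM reads the
sentence twice, once reversed). The two final hidden states are
concatenated into a 2k sentence representation. The decoder is a
separate unidirectional LSTM: its initial hidden and cell states are a
learned linear projection of the 2k representation, it consumes the
embedding of the previous target token (teacher forcing; greedy
feedback when disabled), and a linear output layer plus softmax over
the vocabulary reconstructs the input sequence terminated by EOS.
Trained by SGD on mean token-level cross-entropy over unlabeled
sentences, the encoder's representation serves as a global sentence
feature for downstream classification.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from ._rng import derive_rng
from .batching import iter_batches, pad_batch
from .embeddings import EmbeddingMatrix
from .nn import SGD, Embedding, LSTMCell, Linear, Module, autograd as ag
from .nn.autograd import Tensor
from .records import SentenceRecord, ValidationError
from .vocab import Vocabulary


class TrainingError(RuntimeError):
    """Raised when optimization diverges (non-finite loss)."""


@dataclass(frozen=True)
class AutoencoderConfig:
    hidden_size: int = 64
    embedding_dim: int = 200
    shared_direction_weights: bool = True
    teacher_forcing: bool = True
    epochs: int = 5
    batch_size: int = 16
    learning_rate: float = 0.001
    clip_norm: float | None = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_size < 1:
            raise ValidationError("hidden_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")


@dataclass(frozen=True)
class SentenceRepresentation:
    """Concatenated final encoder states [h_forward ; h_backward], length 2k."""

    vector: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "vector", np.asarray(self.vector, dtype=np.float64))
        if not np.all(np.isfinite(self.vector)):
            raise ValidationError("sentence representation has non-finite entries")


class BiLSTMAutoencoder(Module):
    def __init__(
        self,
        vocab: Vocabulary,
        embeddings: EmbeddingMatrix,
        config: AutoencoderConfig = AutoencoderConfig(),
    ):
        if embeddings.vectors.shape != (len(vocab), config.embedding_dim):
            raise ValidationError(
                f"embedding matrix {embeddings.vectors.shape} does not match "
                f"|V|={len(vocab)}, d={config.embedding_dim}"
            )
        self.vocab = vocab
        self.config = config
        rng = derive_rng(config.seed, "autoencoder_init")
        k, d = config.hidden_size, config.embedding_dim
        self.embedding = Embedding(embeddings.vectors, pad_index=vocab.pad_index)
        self.enc_fwd = LSTMCell(d, k, rng)
        self.enc_bwd = (
            self.enc_fwd if config.shared_direction_weights else LSTMCell(d, k, rng)
        )
        self.proj_h = Linear(2 * k, k, rng)
        self.proj_c = Linear(2 * k, k, rng)
        self.decoder = LSTMCell(d, k, rng)
        # Near-zero output layer: an untrained decoder is near-uniform over
        # the vocabulary, so the initial per-token loss sits at ~ln|V|.
        self.output = Linear(k, len(vocab), rng, scale=0.01)

    # ------------------------------------------------------------- encoding
    def _scan(self, cell: LSTMCell, emb: Tensor, lengths: np.ndarray) -> Tensor:
        B, N = emb.shape[0], emb.shape[1]
        k = self.config.hidden_size
        h = Tensor(np.zeros((B, k)))
        c = Tensor(np.zeros((B, k)))
        for t in range(N):
            x_t = ag.narrow(emb, 1, t, 1)
            x_t = ag.reshape(x_t, (B, emb.shape[2]))
            mask = (t < lengths).astype(np.float64)
            h, c = cell.masked_step(x_t, h, c, mask)
        return h

    def encode_batch(self, idx: np.ndarray, lengths: np.ndarray) -> Tensor:
        """(B, N) indices → (B, 2k) concatenated final states."""
        if idx.shape[0] != lengths.shape[0]:
            raise ValidationError("index batch and lengths disagree")
        emb = self.embedding(idx)
        h_fwd = self._scan(self.enc_fwd, emb, lengths)
        rev = _reverse_within_lengths(idx, lengths, self.vocab.pad_index)
        emb_rev = self.embedding(rev)
        h_bwd = self._scan(self.enc_bwd, emb_rev, lengths)
        return ag.concat([h_fwd, h_bwd], axis=-1)

    def encode(self, indices: Sequence[int]) -> SentenceRepresentation:
        """Sentence representation of one index sequence (inference)."""
        if len(indices) == 0:
            raise ValidationError("cannot encode an empty sequence")
        idx, lengths = pad_batch([list(indices)], self.vocab.pad_index)
        rep = self.encode_batch(idx, lengths)
        return SentenceRepresentation(vector=rep.data[0].copy())

    def encode_many(self, encoded: Sequence[Sequence[int]], batch_size: int = 64) -> np.ndarray:
        """Representations for many sentences, (n, 2k); batch-invariant."""
        reps = np.empty((len(encoded), 2 * self.config.hidden_size))
        for batch in iter_batches(len(encoded), batch_size):
            idx, lengths = pad_batch([list(encoded[i]) for i in batch], self.vocab.pad_index)
            reps[batch] = self.encode_batch(idx, lengths).data
        return reps

    # ------------------------------------------------------------- decoding
    def reconstruction_loss_batch(self, idx: np.ndarray, lengths: np.ndarray) -> Tensor:
        """Mean token cross-entropy reconstructing the batch (scalar)."""
        B, N = idx.shape
        k = self.config.hidden_size
        rep = self.encode_batch(idx, lengths)
        h = self.proj_h(rep)
        c = self.proj_c(rep)
        v = self.vocab
        # decoder inputs: BOS, x_1..x_N ; targets: x_1..x_N, EOS
        dec_in = np.concatenate(
            [np.full((B, 1), v.bos_index, dtype=np.intp), idx], axis=1
        )
        targets = np.concatenate(
            [idx, np.full((B, 1), v.pad_index, dtype=np.intp)], axis=1
        )
        targets[np.arange(B), lengths] = v.eos_index
        steps = int(lengths.max()) + 1
        mask = np.arange(steps)[None, :] < (lengths + 1)[:, None]
        hs: list[Tensor] = []
        prev_pred: np.ndarray | None = None
        for t in range(steps):
            if self.config.teacher_forcing or t == 0 or prev_pred is None:
                x_ids = dec_in[:, t]
            else:
                x_ids = prev_pred
            x_t = self.embedding(x_ids)
            h, c = self.decoder.step(x_t, h, c)
            hs.append(ag.reshape(h, (B, 1, k)))
            if not self.config.teacher_forcing:
                logits_t = self.output(h)
                prev_pred = np.argmax(logits_t.data, axis=-1)
        hidden = ag.concat(hs, axis=1)  # (B, steps, k)
        logits = self.output(hidden)  # (B, steps, V)
        return ag.softmax_cross_entropy(logits, targets[:, :steps], mask)

    def reconstruction_loss(self, indices: Sequence[int]) -> float:
        if len(indices) == 0:
            raise ValidationError("cannot reconstruct an empty sequence")
        idx = np.asarray([list(indices)], dtype=np.intp)
        lengths = np.asarray([len(indices)], dtype=np.intp)
        return float(self.reconstruction_loss_batch(idx, lengths).item())

    def greedy_decode(self, indices: Sequence[int], max_length: int | None = None) -> list[int]:
        """Free-running greedy reconstruction of one sentence's indices."""
        if len(indices) == 0:
            raise ValidationError("cannot decode an empty sequence")
        if max_length is None:
            max_length = 2 * len(indices) + 2
        idx, lengths = pad_batch([list(indices)], self.vocab.pad_index)
        rep = self.encode_batch(idx, lengths)
        h = self.proj_h(rep)
        c = self.proj_c(rep)
        token = self.vocab.bos_index
        out: list[int] = []
        for _ in range(max_length):
            x = self.embedding(np.array([token], dtype=np.intp))
            h, c = self.decoder.step(x, h, c)
            token = int(np.argmax(self.output(h).data[0]))
            if token == self.vocab.eos_index:
                break
            out.append(token)
        return out

    # ----------------------------------------------------------- checkpoint
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = asdict(self.config)
        meta["vocab_hash"] = self.vocab.content_hash()
        (directory / "config.json").write_text(json.dumps(meta, indent=2))
        self.vocab.save(directory / "vocab.json")
        np.savez(directory / "weights.npz", **self.state_arrays())

    @classmethod
    def load(cls, directory: str | Path) -> "BiLSTMAutoencoder":
        directory = Path(directory)
        meta = json.loads((directory / "config.json").read_text())
        vocab = Vocabulary.load(directory / "vocab.json")
        if meta.pop("vocab_hash") != vocab.content_hash():
            raise ValidationError(f"{directory}: vocabulary hash mismatch")
        config = AutoencoderConfig(**meta)
        model = cls(
            vocab,
            EmbeddingMatrix(
                vectors=np.zeros((len(vocab), config.embedding_dim)), source="random"
            ),
            config,
        )
        with np.load(directory / "weights.npz") as arrays:
            model.load_state_arrays(dict(arrays))
        return model


def _reverse_within_lengths(
    idx: np.ndarray, lengths: np.ndarray, pad_index: int
) -> np.ndarray:
    """Reverse each row's first `length` entries, keeping padding in place."""
    out = np.full_like(idx, pad_index)
    for i, n in enumerate(lengths):
        out[i, :n] = idx[i, :n][::-1]
    return out


def pretrain(
    model: BiLSTMAutoencoder,
    pool: Sequence[SentenceRecord],
    config: AutoencoderConfig | None = None,
) -> list[float]:
    """Train the autoencoder to reconstruct the pool; returns loss history.

    Stochastic gradient descent on mean reconstruction cross-entropy with
    seeded per-epoch shuffling; the history has one mean-loss entry per
    epoch. Raises :class:`TrainingError` if the loss becomes non-finite.
    """
    if not pool:
        raise ValidationError("pretraining pool is empty")
    if config is None:
        config = model.config
    encoded = [model.vocab.encode(r.tokens) for r in pool]
    rng = derive_rng(config.seed, "pretrain_shuffle")
    opt = SGD(list(model.parameters()), lr=config.learning_rate, clip_norm=config.clip_norm)
    history: list[float] = []
    for epoch in range(config.epochs):
        total, n_batches = 0.0, 0
        for batch in iter_batches(len(encoded), config.batch_size, rng):
            idx, lengths = pad_batch(
                [encoded[i] for i in batch], model.vocab.pad_index
            )
            loss = model.reconstruction_loss_batch(idx, lengths)
            if not np.isfinite(loss.item()):
                raise TrainingError(f"non-finite reconstruction loss at epoch {epoch + 1}")
            opt.zero_grad()
            loss.backward()
            model.embedding.mask_pad_grad()
            opt.step()
            total += loss.item()
            n_batches += 1
        history.append(total / n_batches)
    return history
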