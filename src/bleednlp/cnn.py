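"""Multi-width convolutional sentence classifier with optional feature fusion.

Token embeddings form an n x d sentence matrix. Filter banks of widths
3, 4 and 5 (10 filters each by default) slide over the rows: each
position yields c_i = tanh(w . [e_i ... e_{i+k-1}] + b), with zero-row
padding when the sentence is shorter than the filter. Max-over-time
pooling keeps one value per filter; the pooled vectors are
concatenated and — in the hybrid configuration — joined with the 2k
sentence representation from the pretrained sequence autoencoder.
Dropout is applied to the concatenated feature vector, then a fully
connected layer and softmax give P(bleeding present); probabilities at
or above the 0.5 cutoff predict positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._rng import derive_rng
from .batching import pad_batch
from .embeddings import EmbeddingMatrix
from .nn import Embedding, Linear, Module, Parameter, autograd as ag, dropout
from .nn.autograd import Tensor
from .records import NEGATIVE, POSITIVE, ValidationError
from .vocab import Vocabulary

NEG_INF = -1e30  # pool mask: tanh features lie in [-1, 1]


@dataclass(frozen=True)
class CNNConfig:
    filter_widths: tuple[int, ...] = (3, 4, 5)
    filters_per_width: int = 10
    dropout_rate: float = 0.3
    embedding_dim: int = 200
    use_autoencoder_features: bool = False
    autoencoder_dim: int = 0  # 2k when fused
    cutoff: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if any(w < 1 for w in self.filter_widths) or not self.filter_widths:
            raise ValidationError("filter widths must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValidationError("dropout_rate must be in [0,1)")
        if not 0.0 < self.cutoff < 1.0:
            raise ValidationError("cutoff must be in (0,1)")
        if self.use_autoencoder_features and self.autoencoder_dim < 1:
            raise ValidationError("fusion requires autoencoder_dim >= 1")

    @property
    def pooled_dim(self) -> int:
        return self.filters_per_width * len(self.filter_widths)

    @property
    def feature_dim(self) -> int:
        return self.pooled_dim + (
            self.autoencoder_dim if self.use_autoencoder_features else 0
        )


def convolve(
    sentence_embeddings: np.ndarray, width: int, filters: np.ndarray,
    bias: np.ndarray | None = None,
) -> np.ndarray:
    """Feature maps of a filter bank over one sentence matrix.

    `sentence_embeddings` is n x d; `filters` is (width*d, F). Sentences
    shorter than the filter are zero-padded to one window. Returns
    (max(n - width + 1, 1), F) with entries tanh(w . window + b).
    """
    E = np.asarray(sentence_embeddings, dtype=np.float64)
    if E.ndim != 2:
        raise ValidationError("sentence matrix must be 2-D")
    n, d = E.shape
    filters = np.asarray(filters, dtype=np.float64)
    if filters.shape[0] != width * d:
        raise ValidationError(
            f"filter rows {filters.shape[0]} != width*d = {width * d}"
        )
    if bias is None:
        bias = np.zeros(filters.shape[1])
    if n < width:
        E = np.vstack([E, np.zeros((width - n, d))])
        n = width
    P = n - width + 1
    windows = np.stack([E[i : i + width].reshape(-1) for i in range(P)])
    return np.tanh(windows @ filters + bias)


def max_pool(feature_map: Sequence[float] | np.ndarray) -> float:
    """Max over time of one filter's feature map."""
    arr = np.asarray(feature_map, dtype=np.float64)
    if arr.size == 0:
        raise ValidationError("cannot max-pool an empty feature map")
    return float(arr.max())


def predict(probability: float, cutoff: float = 0.5) -> str:
    """Binarize P(positive); ties at the cutoff resolve to positive."""
    if not 0.0 < cutoff < 1.0:
        raise ValidationError(f"cutoff must be in (0,1), got {cutoff}")
    if not 0.0 <= probability <= 1.0:
        raise ValidationError(f"probability must be in [0,1], got {probability}")
    return POSITIVE if probability >= cutoff else NEGATIVE


class ConvSentenceClassifier(Module):
    def __init__(
        self,
        vocab: Vocabulary,
        embeddings: EmbeddingMatrix,
        config: CNNConfig = CNNConfig(),
    ):
        if embeddings.vectors.shape != (len(vocab), config.embedding_dim):
            raise ValidationError(
                f"embedding matrix {embeddings.vectors.shape} does not match "
                f"|V|={len(vocab)}, d={config.embedding_dim}"
            )
        self.vocab = vocab
        self.config = config
        rng = derive_rng(config.seed, "cnn_init")
        d, F = config.embedding_dim, config.filters_per_width
        self.embedding = Embedding(embeddings.vectors, pad_index=vocab.pad_index)
        self.conv_weights: list[Parameter] = []
        self.conv_biases: list[Parameter] = []
        for w in config.filter_widths:
            scale = float(np.sqrt(6.0 / (w * d + F)))
            self.conv_weights.append(Parameter(rng.uniform(-scale, scale, (w * d, F))))
            self.conv_biases.append(Parameter(np.zeros(F)))
        self.fc = Linear(config.feature_dim, 2, rng)

    # ------------------------------------------------------------- features
    def features_batch(self, idx: np.ndarray, lengths: np.ndarray) -> Tensor:
        """Pooled convolutional features, (B, filters x widths)."""
        emb = self.embedding(idx)
        B, N = idx.shape
        pooled: list[Tensor] = []
        for w, weight, bias in zip(
            self.config.filter_widths, self.conv_weights, self.conv_biases
        ):
            windows = ag.unfold_windows(emb, w)  # (B, P, w*d)
            fmap = ag.tanh(ag.add(ag.matmul(windows, weight), bias))
            P = N - w + 1
            # positions beyond a sentence's own windows never reach the max
            valid = np.maximum(lengths - w + 1, 1)
            pos_mask = np.where(
                np.arange(P)[None, :] < valid[:, None], 0.0, NEG_INF
            )
            fmap = ag.add(fmap, pos_mask[:, :, None])
            pooled.append(ag.max_along(fmap, axis=1))  # (B, F)
        return ag.concat(pooled, axis=-1)

    def logits_batch(
        self,
        idx: np.ndarray,
        lengths: np.ndarray,
        ae_reps: np.ndarray | None = None,
        train_rng: np.random.Generator | None = None,
    ) -> Tensor:
        feats = self.features_batch(idx, lengths)
        if self.config.use_autoencoder_features:
            if ae_reps is None:
                raise ValidationError(
                    "classifier configured for fusion but no autoencoder "
                    "representations were supplied"
                )
            feats = ag.concat([feats, ag.as_tensor(np.asarray(ae_reps))], axis=-1)
        elif ae_reps is not None:
            raise ValidationError(
                "autoencoder representations supplied but fusion is disabled"
            )
        feats = dropout(feats, self.config.dropout_rate, train_rng)
        return self.fc(feats)

    def probabilities(
        self,
        encoded: Sequence[Sequence[int]],
        ae_reps: np.ndarray | None = None,
        batch_size: int = 64,
    ) -> np.ndarray:
        """P(positive) for each encoded sentence; inference mode."""
        probs = np.empty(len(encoded))
        for start in range(0, len(encoded), batch_size):
            chunk = [list(s) for s in encoded[start : start + batch_size]]
            idx, lengths = pad_batch(
                chunk, self.vocab.pad_index, min_length=max(self.config.filter_widths)
            )
            reps = None if ae_reps is None else ae_reps[start : start + len(chunk)]
            logits = self.logits_batch(idx, lengths, reps)
            probs[start : start + len(chunk)] = ag.softmax(logits.data, axis=-1)[:, 1]
        return probs

    def forward(
        self, indices: Sequence[int], ae_rep: np.ndarray | None = None
    ) -> float:
        """P(positive) for a single sentence (inference, deterministic)."""
        if len(indices) == 0:
            raise ValidationError("cannot classify an empty sequence")
        reps = None if ae_rep is None else np.asarray(ae_rep)[None, :]
        return float(self.probabilities([list(indices)], reps)[0])
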