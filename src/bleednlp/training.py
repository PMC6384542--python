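"""Training orchestration for the neural experiment variants.

Seven named variants share one seeded configuration system:

========  ==========================================================
variant   model
========  ==========================================================
ae_clf    BiLSTM encoder representation + fully connected softmax
ae_clf_pre  same, with pretrained word vectors (fine-tuned)
cnn       multi-width CNN classifier, random embeddings
cnn_pre   CNN with pretrained word vectors (fine-tuned)
hcla      hybrid: CNN features fused with the pretrained
          autoencoder's 2k sentence representation before softmax
cnn_neg   CNN under the negation-bleeding data setting
hcla_neg  hybrid under the negation-bleeding data setting
========  ==========================================================

The hybrid variants first pretrain (or load) the sequence autoencoder
on an unlabeled pool that must not overlap the test sentences — a
leakage guard asserts this at train time. Classification training
minimizes two-class cross-entropy with plain SGD; the best epoch is
selected on a stratified validation carve-out of the training data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from ._rng import derive_rng
from .autoencoder import (
    AutoencoderConfig,
    BiLSTMAutoencoder,
    TrainingError,
    pretrain,
)
from .batching import iter_batches, pad_batch
from .cnn import CNNConfig, ConvSentenceClassifier, predict as binarize
from .corpus import split_train_test
from .embeddings import EmbeddingMatrix, init_embeddings, load_pretrained
from .nn import SGD, Linear, Module, autograd as ag, dropout
from .records import (
    NEGATIVE,
    POSITIVE,
    CorpusSplit,
    SentenceRecord,
    ValidationError,
)
from .vocab import Vocabulary, build_vocab

VARIANTS = ("ae_clf", "ae_clf_pre", "cnn", "cnn_pre", "hcla", "cnn_neg", "hcla_neg")
_PRETRAINED_VARIANTS = ("ae_clf_pre", "cnn_pre")
_HYBRID_VARIANTS = ("hcla", "hcla_neg")
_RECURRENT_VARIANTS = ("ae_clf", "ae_clf_pre")


class ConfigurationError(ValueError):
    """A variant was configured without a required ingredient."""


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters shared by all variants.

    Defaults: 200-dimensional embeddings,
    64 hidden units, dropout 0.3 on the feature vector, batch size 16,
    learning rate 0.001 with plain SGD, filter widths 3/4/5 with 10
    filters each, decision cutoff 0.5. Epoch count and model selection
    are open choices: default 30 epochs with best-epoch selection on a
    10% validation carve-out.
    """

    variant: str = "cnn"
    embedding_dim: int = 200
    hidden_size: int = 64
    filter_widths: tuple[int, ...] = (3, 4, 5)
    filters_per_width: int = 10
    dropout_rate: float = 0.3
    learning_rate: float = 0.001
    batch_size: int = 16
    epochs: int = 30
    seed: int = 0
    cutoff: float = 0.5
    val_fraction: float = 0.1
    min_freq: int = 1
    freeze_encoder: bool = True
    freeze_embeddings: bool = False
    ae_epochs: int = 5
    ae_learning_rate: float | None = None
    clip_norm: float | None = 5.0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ConfigurationError(
                f"unknown variant {self.variant!r}; expected one of {VARIANTS}"
            )
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValidationError("learning_rate, batch_size, epochs must be positive")


class RecurrentSentenceClassifier(Module):
    """BiLSTM encoder + fully connected softmax head (no convolution)."""

    def __init__(self, autoencoder: BiLSTMAutoencoder, dropout_rate: float, seed: int):
        self.autoencoder = autoencoder
        self.dropout_rate = dropout_rate
        rng = derive_rng(seed, "recurrent_head_init")
        self.head = Linear(2 * autoencoder.config.hidden_size, 2, rng)

    def logits_batch(
        self,
        idx: np.ndarray,
        lengths: np.ndarray,
        train_rng: np.random.Generator | None = None,
    ):
        rep = self.autoencoder.encode_batch(idx, lengths)
        rep = dropout(rep, self.dropout_rate, train_rng)
        return self.head(rep)

    def probabilities(self, encoded, batch_size: int = 64) -> np.ndarray:
        probs = np.empty(len(encoded))
        for start in range(0, len(encoded), batch_size):
            chunk = [list(s) for s in encoded[start : start + batch_size]]
            idx, lengths = pad_batch(chunk, self.autoencoder.vocab.pad_index)
            logits = self.logits_batch(idx, lengths)
            probs[start : start + len(chunk)] = ag.softmax(logits.data, axis=-1)[:, 1]
        return probs


@dataclass
class ModelBundle:
    """A trained variant: vocabulary, classifier, optional autoencoder."""

    variant: str
    vocab: Vocabulary
    classifier: ConvSentenceClassifier | RecurrentSentenceClassifier
    autoencoder: BiLSTMAutoencoder | None
    config: TrainConfig

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = asdict(self.config)
        meta["vocab_hash"] = self.vocab.content_hash()
        (directory / "config.json").write_text(json.dumps(meta, indent=2))
        self.vocab.save(directory / "vocab.json")
        np.savez(directory / "classifier.npz", **self.classifier.state_arrays())
        if self.autoencoder is not None:
            self.autoencoder.save(directory / "autoencoder")

    @classmethod
    def load(cls, directory: str | Path) -> "ModelBundle":
        directory = Path(directory)
        meta = json.loads((directory / "config.json").read_text())
        vocab_hash = meta.pop("vocab_hash")
        meta["filter_widths"] = tuple(meta["filter_widths"])
        config = TrainConfig(**meta)
        vocab = Vocabulary.load(directory / "vocab.json")
        if vocab.content_hash() != vocab_hash:
            raise ValidationError(f"{directory}: vocabulary hash mismatch")
        autoencoder = None
        if (directory / "autoencoder").exists():
            autoencoder = BiLSTMAutoencoder.load(directory / "autoencoder")
        classifier = _build_classifier(config, vocab, _zero_embeddings(config, vocab))
        with np.load(directory / "classifier.npz") as arrays:
            classifier.load_state_arrays(dict(arrays))
        if isinstance(classifier, RecurrentSentenceClassifier) and autoencoder is not None:
            classifier.autoencoder = autoencoder
        return cls(
            variant=config.variant,
            vocab=vocab,
            classifier=classifier,
            autoencoder=autoencoder,
            config=config,
        )


def _zero_embeddings(config: TrainConfig, vocab: Vocabulary) -> EmbeddingMatrix:
    return EmbeddingMatrix(
        vectors=np.zeros((len(vocab), config.embedding_dim)), source="random"
    )


def _build_classifier(config: TrainConfig, vocab: Vocabulary, emb: EmbeddingMatrix):
    if config.variant in _RECURRENT_VARIANTS:
        ae = BiLSTMAutoencoder(
            vocab,
            emb,
            AutoencoderConfig(
                hidden_size=config.hidden_size,
                embedding_dim=config.embedding_dim,
                seed=config.seed,
            ),
        )
        return RecurrentSentenceClassifier(ae, config.dropout_rate, config.seed)
    fused = config.variant in _HYBRID_VARIANTS
    cnn_config = CNNConfig(
        filter_widths=tuple(config.filter_widths),
        filters_per_width=config.filters_per_width,
        dropout_rate=config.dropout_rate,
        embedding_dim=config.embedding_dim,
        use_autoencoder_features=fused,
        autoencoder_dim=2 * config.hidden_size if fused else 0,
        cutoff=config.cutoff,
        seed=config.seed,
    )
    return ConvSentenceClassifier(vocab, emb, cnn_config)


def _labels_to_targets(records: Sequence[SentenceRecord]) -> np.ndarray:
    for r in records:
        if r.label not in (POSITIVE, NEGATIVE):
            raise ValidationError(
                f"training requires labeled records; {r.sentence_id} is {r.label!r}"
            )
    return np.array([1 if r.label == POSITIVE else 0 for r in records], dtype=np.intp)


def train(
    config: TrainConfig,
    split: CorpusSplit,
    unlabeled_pool: Sequence[SentenceRecord] | None = None,
    pretrained_vectors: str | Path | None = None,
    ae_checkpoint: str | Path | None = None,
) -> tuple[ModelBundle, dict]:
    """Train one experiment variant; returns the bundle and a training log.

    The autoencoder of the hybrid variants is pretrained on
    `unlabeled_pool` (or loaded from `ae_checkpoint`); the pool must not
    contain any test sentence_id. Fully seeded and deterministic in
    single-threaded mode.
    """
    if not split.train:
        raise ValidationError("training split is empty")
    variant = config.variant
    if variant in _PRETRAINED_VARIANTS and pretrained_vectors is None:
        raise ConfigurationError(f"variant {variant!r} requires pretrained vectors")
    if variant in _HYBRID_VARIANTS and unlabeled_pool is None and ae_checkpoint is None:
        raise ConfigurationError(
            f"variant {variant!r} requires an unlabeled pool or an "
            "autoencoder checkpoint"
        )
    if unlabeled_pool:
        test_ids = {r.sentence_id for r in split.test}
        leaked = [r.sentence_id for r in unlabeled_pool if r.sentence_id in test_ids]
        if leaked:
            raise ValidationError(
                f"unlabeled pool contains {len(leaked)} test sentence(s), "
                f"e.g. {leaked[0]!r}: test data must not reach pretraining"
            )

    vocab_source = list(split.train) + list(unlabeled_pool or [])
    vocab = build_vocab(vocab_source, min_freq=config.min_freq)
    if pretrained_vectors is not None:
        emb = load_pretrained(
            pretrained_vectors, vocab, dim=config.embedding_dim, seed=config.seed
        )
    else:
        emb = init_embeddings(vocab, dim=config.embedding_dim, seed=config.seed)

    log: dict = {"variant": variant, "train_loss": [], "val_accuracy": []}

    autoencoder: BiLSTMAutoencoder | None = None
    if variant in _HYBRID_VARIANTS:
        if ae_checkpoint is not None:
            autoencoder = BiLSTMAutoencoder.load(ae_checkpoint)
            if autoencoder.vocab.content_hash() != vocab.content_hash():
                raise ValidationError(
                    "autoencoder checkpoint vocabulary does not match this corpus"
                )
        else:
            ae_config = AutoencoderConfig(
                hidden_size=config.hidden_size,
                embedding_dim=config.embedding_dim,
                epochs=config.ae_epochs,
                batch_size=config.batch_size,
                learning_rate=config.ae_learning_rate or config.learning_rate,
                clip_norm=config.clip_norm,
                seed=config.seed,
            )
            autoencoder = BiLSTMAutoencoder(vocab, emb, ae_config)
            # pretraining pool: unlabeled sentences plus the (non-test)
            # training sentences, mirroring "all remaining sentences"
            pool = list(unlabeled_pool or []) + list(split.train)
            log["ae_loss"] = pretrain(autoencoder, pool, ae_config)

    classifier = _build_classifier(config, vocab, emb)

    # validation carve-out for best-epoch selection
    if 0.0 < config.val_fraction < 1.0 and len(split.train) >= 20:
        inner = split_train_test(
            split.train,
            test_fraction=config.val_fraction,
            seed=config.seed + 1,
            stratify=len({r.label for r in split.train}) > 1,
        )
        fit_records, val_records = list(inner.train), list(inner.test)
    else:
        fit_records, val_records = list(split.train), []

    encoded_fit = [vocab.encode(r.tokens) for r in fit_records]
    targets_fit = _labels_to_targets(fit_records)
    encoded_val = [vocab.encode(r.tokens) for r in val_records]
    targets_val = _labels_to_targets(val_records) if val_records else np.empty(0)

    joint = isinstance(classifier, ConvSentenceClassifier) and autoencoder is not None
    frozen_reps_fit = frozen_reps_val = None
    if joint and config.freeze_encoder:
        frozen_reps_fit = autoencoder.encode_many(encoded_fit)
        frozen_reps_val = autoencoder.encode_many(encoded_val) if val_records else None

    params = list(classifier.parameters())
    if joint and not config.freeze_encoder:
        params += list(autoencoder.parameters())
    if config.freeze_embeddings:
        emb_params = {id(classifier.embedding.weight)} if hasattr(classifier, "embedding") else set()
        if isinstance(classifier, RecurrentSentenceClassifier):
            emb_params = {id(classifier.autoencoder.embedding.weight)}
        params = [p for p in params if id(p) not in emb_params]
    opt = SGD(params, lr=config.learning_rate, clip_norm=config.clip_norm)
    shuffle_rng = derive_rng(config.seed, "train_shuffle")
    dropout_rng = derive_rng(config.seed, "train_dropout")
    min_len = (
        max(config.filter_widths)
        if isinstance(classifier, ConvSentenceClassifier)
        else 1
    )

    best_acc, best_loss, best_weights, best_epoch = -1.0, np.inf, None, 0
    for epoch in range(config.epochs):
        total, n_batches = 0.0, 0
        for batch in iter_batches(len(encoded_fit), config.batch_size, shuffle_rng):
            idx, lengths = pad_batch(
                [encoded_fit[i] for i in batch], vocab.pad_index, min_length=min_len
            )
            if isinstance(classifier, ConvSentenceClassifier):
                if joint and not config.freeze_encoder:
                    reps = autoencoder.encode_batch(idx, lengths)
                elif joint:
                    reps = frozen_reps_fit[batch]
                else:
                    reps = None
                logits = classifier.logits_batch(idx, lengths, reps, dropout_rng)
            else:
                logits = classifier.logits_batch(idx, lengths, dropout_rng)
            loss = ag.softmax_cross_entropy(logits, targets_fit[batch])
            if not np.isfinite(loss.item()):
                raise TrainingError(f"non-finite training loss at epoch {epoch + 1}")
            opt.zero_grad()
            loss.backward()
            _mask_pad_grads(classifier, autoencoder)
            opt.step()
            total += loss.item()
            n_batches += 1
        log["train_loss"].append(total / n_batches)

        if val_records:
            val_scores = _scores(classifier, encoded_val, frozen_reps_val, autoencoder)
            acc = float(((val_scores >= config.cutoff) == (targets_val == 1)).mean())
            log["val_accuracy"].append(acc)
            epoch_loss = log["train_loss"][-1]
            # ties on the small validation set break toward lower train loss
            if acc > best_acc or (acc == best_acc and epoch_loss < best_loss):
                best_acc, best_loss, best_epoch = acc, epoch_loss, epoch
                best_weights = classifier.copy_weights()

    if best_weights is not None:
        classifier.restore_weights(best_weights)
    log["best_epoch"] = best_epoch + 1 if val_records else config.epochs

    bundle = ModelBundle(
        variant=variant,
        vocab=vocab,
        classifier=classifier,
        autoencoder=autoencoder,
        config=config,
    )
    return bundle, log


def _mask_pad_grads(classifier, autoencoder) -> None:
    if hasattr(classifier, "embedding"):
        classifier.embedding.mask_pad_grad()
    if isinstance(classifier, RecurrentSentenceClassifier):
        classifier.autoencoder.embedding.mask_pad_grad()
    if autoencoder is not None:
        autoencoder.embedding.mask_pad_grad()


def _scores(classifier, encoded, frozen_reps, autoencoder) -> np.ndarray:
    if isinstance(classifier, ConvSentenceClassifier):
        if classifier.config.use_autoencoder_features:
            reps = (
                frozen_reps
                if frozen_reps is not None
                else autoencoder.encode_many(encoded)
            )
            return classifier.probabilities(encoded, reps)
        return classifier.probabilities(encoded)
    return classifier.probabilities(encoded)


def predict_corpus(
    bundle: ModelBundle, records: Sequence[SentenceRecord]
) -> tuple[np.ndarray, list[str]]:
    """Probabilities and binarized labels for each record, input order.

    Results are batch-size independent: padding is masked out of both
    the recurrent scans and the pooled convolution windows.
    """
    if not records:
        return np.empty(0), []
    encoded = [bundle.vocab.encode(r.tokens) for r in records]
    scores = _scores(bundle.classifier, encoded, None, bundle.autoencoder)
    labels = [binarize(float(s), bundle.config.cutoff) for s in scores]
    return scores, labels
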