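"""Training orchestration: variants, determinism, leakage guard, prediction."""

import numpy as np
import pytest

from bleednlp.corpus import split_train_test
from bleednlp.embeddings import init_embeddings, save_glove_text
from bleednlp.records import CorpusSplit, ValidationError
from bleednlp.synthetic import GeneratorConfig, generate_corpus, generate_unlabeled_pool
from bleednlp.training import (
    ConfigurationError,
    ModelBundle,
    RecurrentSentenceClassifier,
    TrainConfig,
    predict_corpus,
    train,
)
from bleednlp.cnn import ConvSentenceClassifier
from bleednlp.evaluation import evaluate


def small_split(seed=5, n_notes=6):
    cfg = GeneratorConfig(
        n_notes=n_notes,
        sentences_per_note=(18, 22),
        positive_prevalence=0.5,
        negated_fraction_of_bleeding_mentions=0.0,
        fragment_rate=0.0,
        duplicate_rate=0.0,
        seed=seed,
    )
    corpus = generate_corpus(cfg)
    return split_train_test(corpus, 0.2, seed=seed), cfg


def quick_config(variant, **kw):
    defaults = dict(
        variant=variant,
        embedding_dim=16,
        hidden_size=8,
        filters_per_width=4,
        epochs=3,
        learning_rate=0.05,
        ae_epochs=1,
        seed=11,
    )
    defaults.update(kw)
    return TrainConfig(**defaults)


class TestTrainVariants:
    def test_cnn_bundle_has_no_autoencoder(self):
        split, _ = small_split()
        bundle, log = train(quick_config("cnn", epochs=2), split)
        assert isinstance(bundle.classifier, ConvSentenceClassifier)
        assert bundle.autoencoder is None
        assert len(log["train_loss"]) == 2

    def test_hcla_trains_below_chance_loss(self):
        split, gcfg = small_split(n_notes=12)
        pool = generate_unlabeled_pool(gcfg, 100)
        bundle, log = train(
            quick_config("hcla", epochs=8, ae_epochs=2, ae_learning_rate=0.3),
            split,
            unlabeled_pool=pool,
        )
        assert bundle.autoencoder is not None
        assert log["train_loss"][-1] < np.log(2)

    def test_ae_clf_bundle_is_recurrent(self):
        split, _ = small_split()
        bundle, _ = train(quick_config("ae_clf", epochs=2), split)
        assert isinstance(bundle.classifier, RecurrentSentenceClassifier)

    def test_pretrained_variants_load_vector_file(self, tmp_path):
        split, _ = small_split()
        # vector file covering part of the corpus vocabulary
        tokens = sorted({t for r in split.train for t in r.tokens})[:30]
        rng = np.random.default_rng(0)
        save_glove_text(tmp_path / "v.txt", tokens, rng.normal(size=(30, 16)))
        bundle, _ = train(
            quick_config("cnn_pre", epochs=2),
            split,
            pretrained_vectors=tmp_path / "v.txt",
        )
        assert isinstance(bundle.classifier, ConvSentenceClassifier)

    def test_bitwise_deterministic_weights(self):
        split, _ = small_split()
        runs = []
        for _ in range(2):
            bundle, log = train(quick_config("cnn", epochs=2), split)
            runs.append((bundle.classifier.copy_weights(), log["train_loss"]))
        assert runs[0][1] == runs[1][1]
        for a, b in zip(runs[0][0], runs[1][0]):
            np.testing.assert_array_equal(a, b)


class TestGuards:
    def test_hybrid_requires_pool_or_checkpoint(self):
        split, _ = small_split()
        with pytest.raises(ConfigurationError):
            train(quick_config("hcla"), split)

    def test_pretrained_variant_requires_vectors(self):
        split, _ = small_split()
        with pytest.raises(ConfigurationError):
            train(quick_config("cnn_pre"), split)

    def test_leakage_guard_rejects_test_sentences_in_pool(self):
        split, _ = small_split()
        poisoned = list(split.test[:1])
        with pytest.raises(ValidationError, match="pool"):
            train(quick_config("hcla"), split, unlabeled_pool=poisoned)


@pytest.fixture(scope="module")
def trained():
    split, _ = small_split()
    bundle, _ = train(quick_config("cnn", epochs=2), split)
    return bundle, split


class TestPredictCorpus:
    def test_empty_input(self, trained):
        bundle, _ = trained
        scores, labels = predict_corpus(bundle, [])
        assert len(scores) == 0 and labels == []

    def test_alignment_and_order(self, trained):
        bundle, split = trained
        scores, labels = predict_corpus(bundle, list(split.test))
        assert len(scores) == len(labels) == len(split.test)

    def test_batch_size_invariance(self, trained):
        bundle, split = trained
        records = list(split.test)
        encoded = [bundle.vocab.encode(r.tokens) for r in records]
        one = bundle.classifier.probabilities(encoded, batch_size=1)
        sixteen = bundle.classifier.probabilities(encoded, batch_size=16)
        np.testing.assert_allclose(one, sixteen, atol=1e-6)

    def test_bundle_save_load_same_predictions(self, trained, tmp_path):
        bundle, split = trained
        scores, _ = predict_corpus(bundle, list(split.test))
        bundle.save(tmp_path / "m")
        back = ModelBundle.load(tmp_path / "m")
        scores2, _ = predict_corpus(back, list(split.test))
        np.testing.assert_array_equal(scores, scores2)

    def test_vocab_hash_mismatch_rejected(self, trained, tmp_path):
        from bleednlp.vocab import build_vocab
        from conftest import make_record

        bundle, _ = trained
        bundle.save(tmp_path / "m")
        other = build_vocab([make_record("unrelated tokens entirely new")])
        other.save(tmp_path / "m" / "vocab.json")
        with pytest.raises(ValidationError, match="hash"):
            ModelBundle.load(tmp_path / "m")


class TestNegationSettingTraining:
    def test_single_class_test_set_evaluates_accuracy(self):
        """Negation-setting test sets are all-negative; AUC is omitted."""
        from bleednlp.corpus import make_negation_setting
        from bleednlp.records import NEGATIVE, POSITIVE

        cfg = GeneratorConfig(
            n_notes=10,
            sentences_per_note=(18, 22),
            positive_prevalence=0.35,
            negated_fraction_of_bleeding_mentions=0.4,
            fragment_rate=0.0,
            duplicate_rate=0.0,
            seed=3,
        )
        corpus = generate_corpus(cfg)
        positives = [r for r in corpus if r.label == POSITIVE]
        negated = [r for r in corpus if r.is_negated_bleeding]
        split = make_negation_setting(
            positives, negated, n_train_neg=len(negated) - 10, seed=1
        )
        bundle, _ = train(quick_config("cnn_neg", epochs=4), split)
        with pytest.warns(UserWarning):  # no positives in test -> zero denominators
            report = evaluate(bundle, list(split.test))
        assert report.auc_roc is None
        assert 0.0 <= report.per_class[NEGATIVE]["recall"] <= 1.0
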