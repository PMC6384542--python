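"""Train the CNN and hybrid classifiers and compare their reports.

The workflow runs the full experimental protocol on synthetic data:
generate, preprocess, balance, split 9:1, pretrain the autoencoder on
an unlabeled pool (hybrid only), train, and evaluate per-class and
overall precision/recall/F plus AUC-ROC on the held-out tenth.
"""

from bleednlp import (
    GeneratorConfig,
    TrainConfig,
    balance_downsample,
    evaluate,
    format_report_table,
    generate_corpus,
    generate_unlabeled_pool,
    preprocess,
    split_train_test,
    train,
)

gen = GeneratorConfig(
    n_notes=60,
    sentences_per_note=(30, 40),
    positive_prevalence=0.18,
    negated_fraction_of_bleeding_mentions=0.25,
    fragment_rate=0.03,
    duplicate_rate=0.02,
    negation_style="mixed",
    seed=1,
)
corpus, _ = preprocess(generate_corpus(gen))
positives = [r for r in corpus if r.label == "positive"]
hard = [r for r in corpus if r.is_negated_bleeding][: len(positives)]
neg_pool = [r for r in corpus if r.label == "negative" and not r.is_negated_bleeding]
balanced = balance_downsample(positives, hard, neg_pool, seed=1)
split = split_train_test(balanced, test_fraction=0.1, seed=1)
pool = generate_unlabeled_pool(gen, 400)
print(f"balanced corpus: {len(balanced)} sentences; test: {len(split.test)}")

reports = {}
for variant in ("cnn", "hcla"):
    config = TrainConfig(
        variant=variant, epochs=15, learning_rate=0.05,
        ae_epochs=6, ae_learning_rate=0.5, seed=1,
    )
    bundle, log = train(
        config, split, unlabeled_pool=pool if variant == "hcla" else None
    )
    reports[variant] = evaluate(bundle, list(split.test))
    print(f"{variant}: best epoch {log['best_epoch']}, "
          f"final train loss {log['train_loss'][-1]:.4f}")

print()
print(format_report_table(reports))
# Columns: per-class precision/recall/F for positive and negative
# sentences, the micro-averaged overall metrics (identical by
# construction for binary labels), and AUC-ROC. The hybrid variant
# fuses the autoencoder's global sentence vector with the CNN's local
# features before the softmax layer.
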