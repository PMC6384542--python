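"""The data-balancing protocol at full corpus scale.

From 1451 positive sentences and 285 negated-bleeding hard negatives,
downsampling keeps every positive and every hard negative and samples
just enough additional negatives for a 50/50 corpus; one sentence in
ten is then held out for testing. The negation-bleeding setting
instead trains on 185 of the hard negatives and tests on the rest.
"""

from bleednlp import (
    SentenceRecord,
    balance_downsample,
    make_negation_setting,
    split_train_test,
)


def mk(prefix, i, label, negated=False):
    return SentenceRecord(
        note_id=f"{prefix}{i}",
        sentence_id=f"{prefix}-{i:05d}",
        tokens=(prefix, "sentence", str(i), "tok", "tok"),
        label=label,
        is_negated_bleeding=negated,
    )


positives = [mk("pos", i, "positive") for i in range(1451)]
hard = [mk("hard", i, "negative", negated=True) for i in range(285)]
pool = [mk("neg", i, "negative") for i in range(5000)]

balanced = balance_downsample(positives, hard, pool, seed=7)
sampled = len(balanced) - len(positives) - len(hard)
print(f"positives        : {len(positives)}")
print(f"hard negatives   : {len(hard)}  (kept in full)")
print(f"sampled negatives: {sampled}")
print(f"balanced corpus  : {len(balanced)} sentences, 50% positive")

split = split_train_test(balanced, test_fraction=0.1, seed=7)
print(f"train/test       : {len(split.train)} / {len(split.test)}  (1 in 10 held out)")

negation = make_negation_setting(positives, hard, n_train_neg=185, seed=7)
print(
    f"negation setting : {len(negation.train)} train "
    f"(1451 positive + 185 negated), {len(negation.test)} negated test"
)
# 1166 sampled negatives and a 2902-sentence balanced corpus reproduce
# the protocol arithmetic exactly; the negation setting holds out 100
# negated sentences as its dedicated test set.
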