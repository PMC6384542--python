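"""Evaluation metrics against brute-force and library oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bleednlp.evaluation import (
    ConfusionCounts,
    auc_roc,
    confusion_counts,
    evaluate_predictions,
    format_report_table,
    prf,
)
from bleednlp.records import NEGATIVE, POSITIVE, ValidationError

P, N = POSITIVE, NEGATIVE


class TestConfusion:
    def test_perfect_agreement(self):
        c = confusion_counts([P, N, P], [P, N, P])
        assert (c.tp, c.tn, c.fp, c.fn) == (2, 1, 0, 0)

    def test_all_false_positive(self):
        c = confusion_counts([P] * 4, [N] * 4)
        assert (c.tp, c.fp, c.fn, c.tn) == (0, 4, 0, 0)

    def test_matches_per_item_tally_on_random_vectors(self, rng):
        preds = [P if b else N for b in rng.random(50) < 0.5]
        truths = [P if b else N for b in rng.random(50) < 0.5]
        c = confusion_counts(preds, truths)
        tally = {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
        for p, t in zip(preds, truths):
            key = ("t" if p == t else "f") + ("p" if p == P else "n")
            tally[key] += 1
        assert (c.tp, c.fp, c.fn, c.tn) == (
            tally["tp"], tally["fp"], tally["fn"], tally["tn"],
        )

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            confusion_counts([P], [P, N])


class TestPRF:
    def test_hand_arithmetic(self):
        p, r, f = prf(ConfusionCounts(tp=2, fp=1, fn=1, tn=0))
        assert (p, r, f) == pytest.approx((2 / 3, 2 / 3, 2 / 3))

    def test_zero_denominator_convention(self):
        with pytest.warns(UserWarning):
            p, r, f = prf(ConfusionCounts(tp=0, fp=0, fn=0, tn=5))
        assert (p, r, f) == (0.0, 0.0, 0.0)

    def test_perfect(self):
        assert prf(ConfusionCounts(tp=3, fp=0, fn=0, tn=4)) == (1.0, 1.0, 1.0)

    def test_class_swap_under_label_inversion(self, rng):
        preds = [P if b else N for b in rng.random(40) < 0.6]
        truths = [P if b else N for b in rng.random(40) < 0.4]
        c = confusion_counts(preds, truths)
        inv = confusion_counts(
            [N if p == P else P for p in preds], [N if t == P else P for t in truths]
        )
        assert prf(c, positive_class=NEGATIVE) == prf(inv, positive_class=POSITIVE)


class TestAUC:
    def test_perfect_separation(self):
        assert auc_roc([0.9, 0.8, 0.2, 0.1], [P, P, N, N]) == 1.0

    def test_all_ties_is_half(self):
        assert auc_roc([0.5] * 6, [P, N, P, N, P, N]) == 0.5

    def test_matches_pairwise_oracle_on_random_vectors(self, rng):
        scores = np.round(rng.random(20), 1)  # rounding forces ties
        truths = [P if b else N for b in rng.random(20) < 0.5]
        if P not in truths or N not in truths:
            truths[0], truths[1] = P, N
        pos = [s for s, t in zip(scores, truths) if t == P]
        neg = [s for s, t in zip(scores, truths) if t == N]
        oracle = np.mean(
            [(sp > sn) + 0.5 * (sp == sn) for sp in pos for sn in neg]
        )
        assert auc_roc(scores, truths) == pytest.approx(oracle)

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.random(60)
        truths = [P if b else N for b in rng.random(60) < 0.4]
        if P not in truths or N not in truths:
            truths[0], truths[1] = P, N
        y = [t == P for t in truths]
        assert auc_roc(scores, truths) == pytest.approx(roc_auc_score(y, scores))

    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=4, max_size=30),
        st.integers(0, 2**30),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_invariant_under_monotone_transform(self, scores, seed):
        r = np.random.default_rng(seed)
        truths = [P if b else N for b in r.random(len(scores)) < 0.5]
        if P not in truths:
            truths[0] = P
        if N not in truths:
            truths[-1] = N
        base = auc_roc(scores, truths)
        # power-of-two scaling is exact in binary floating point, so the
        # transform is strictly monotone and preserves the tie structure
        transformed = [4.0 * s for s in scores]
        assert auc_roc(transformed, truths) == pytest.approx(base)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            auc_roc([0.2, 0.8], [P, P])


class TestReport:
    def test_micro_overall_equals_accuracy(self, rng):
        preds = [P if b else N for b in rng.random(30) < 0.5]
        truths = [P if b else N for b in rng.random(30) < 0.5]
        rep = evaluate_predictions(preds, truths)
        assert (
            rep.overall["precision"]
            == rep.overall["recall"]
            == rep.overall["f_score"]
            == rep.accuracy
        )

    def test_component_composition_on_toy_scores(self):
        scores = [0.9, 0.8, 0.7, 0.6, 0.55, 0.45, 0.3, 0.2, 0.15, 0.1]
        truths = [P, P, P, N, P, N, P, N, N, N]
        preds = [P if s >= 0.5 else N for s in scores]
        rep = evaluate_predictions(preds, truths, scores=scores)
        c = confusion_counts(preds, truths)
        for cls in (P, N):
            assert rep.per_class[cls]["precision"] == prf(c, cls)[0]
            assert rep.per_class[cls]["recall"] == prf(c, cls)[1]
        assert rep.auc_roc == pytest.approx(auc_roc(scores, truths))
        assert rep.confusion.n == 10

    def test_perfect_model_all_ones(self):
        truths = [P, N, P, N]
        rep = evaluate_predictions(truths, truths, scores=[0.9, 0.1, 0.8, 0.2])
        assert rep.accuracy == 1.0 and rep.auc_roc == 1.0
        assert all(
            v == 1.0 for cls in rep.per_class.values() for v in cls.values()
        )

    def test_imbalanced_corpus_accuracy_differs_from_positive_f(self, rng):
        # ~97% negative: accuracy is high while positive-class F is not
        truths = [P] * 3 + [N] * 97
        preds = [N] * 100
        with pytest.warns(UserWarning):
            rep = evaluate_predictions(preds, truths)
        assert rep.accuracy == pytest.approx(0.97)
        assert rep.per_class[P]["f_score"] == 0.0

    def test_macro_average_flag(self):
        rep = evaluate_predictions([P, P, N], [P, N, N], average="macro")
        pos, neg = rep.per_class[P], rep.per_class[N]
        assert rep.overall["precision"] == pytest.approx(
            (pos["precision"] + neg["precision"]) / 2
        )

    def test_table_format_lists_all_columns(self):
        rep = evaluate_predictions([P, N], [P, N], scores=[0.8, 0.1])
        table = format_report_table({"cnn": rep})
        assert "Pos-F" in table and "AUC" in table and "cnn" in table
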