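"""Corpus I/O, preprocessing filters, balancing, and split protocols."""

import json

import pytest
from hypothesis import given, settings, strategies as st

from bleednlp.corpus import (
    CorpusParseError,
    balance_downsample,
    make_negation_setting,
    preprocess,
    read_corpus,
    split_train_test,
    tokenize,
    write_corpus,
)
from bleednlp.records import NEGATIVE, POSITIVE, UNLABELED, ValidationError

from conftest import make_record


class TestTokenize:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("No bleeding problems.", ["no", "bleeding", "problems", "."]),
            ("", []),
            ("GI bleed, resolved", ["gi", "bleed", ",", "resolved"]),
            ("heme-positive stools", ["heme-positive", "stools"]),
        ],
    )
    def test_examples(self, text, expected):
        assert tokenize(text) == expected

    @given(st.text(max_size=80))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_deterministic_and_lowercase(self, text):
        toks = tokenize(text)
        assert toks == tokenize(text)
        assert all(t == t.lower() for t in toks)


class TestReadWrite:
    def test_jsonl_text_row(self, tmp_path):
        p = tmp_path / "c.jsonl"
        p.write_text(
            '{"text":"Patient was admitted with hematemesis","label":"positive"}\n'
        )
        (rec,) = read_corpus(p)
        assert rec.label == POSITIVE
        assert len(rec.tokens) == 5

    def test_empty_file(self, tmp_path):
        p = tmp_path / "c.jsonl"
        p.write_text("")
        assert read_corpus(p) == []

    def test_plaintext(self, tmp_path):
        p = tmp_path / "pool.txt"
        p.write_text("one sentence here\nanother one\na third line\n")
        recs = read_corpus(p)
        assert len(recs) == 3
        assert all(r.label == UNLABELED for r in recs)
        assert recs[0].tokens == ("one", "sentence", "here")

    def test_csv(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text(
            "note_id,sentence_id,text,label,is_negated_bleeding\n"
            "n1,s1,no bleeding problems today,negative,true\n"
            "n1,s2,active gi bleed noted,positive,false\n"
        )
        recs = read_corpus(p)
        assert [r.label for r in recs] == [NEGATIVE, POSITIVE]
        assert recs[0].is_negated_bleeding and not recs[1].is_negated_bleeding

    def test_malformed_jsonl_names_line(self, tmp_path):
        p = tmp_path / "c.jsonl"
        p.write_text('{"text":"fine sentence","label":"negative"}\nnot json\n')
        with pytest.raises(CorpusParseError, match=":2:"):
            read_corpus(p)

    def test_unknown_label_rejected(self, tmp_path):
        p = tmp_path / "c.jsonl"
        p.write_text('{"text":"some sentence","label":"maybe"}\n')
        with pytest.raises(ValidationError, match="maybe"):
            read_corpus(p)

    def test_roundtrip(self, tmp_path, small_labeled_corpus):
        p = tmp_path / "c.jsonl"
        write_corpus(small_labeled_corpus, p)
        back = read_corpus(p)
        assert back == small_labeled_corpus


class TestPreprocess:
    def test_duplicates_and_fragments(self, mk):
        a = mk("one two three four five six")
        b = mk("one two three four five six")  # exact duplicate of a
        c = mk("too short here")
        kept, report = preprocess([a, b, c])
        assert kept == [a]
        assert report.n_duplicates_removed == 1
        assert report.n_short_removed == 1

    def test_empty_input(self):
        kept, report = preprocess([])
        assert kept == [] and report.n_input == 0

    def test_planted_fixture_matches_brute_force(self, mk):
        """100 records with 10 planted duplicates and 7 fragments -> 83."""
        base = [mk(f"unique sentence number {i} with padding words") for i in range(83)]
        dups = [
            make_record(base[i].tokens, base[i].label) for i in range(10)
        ]
        frags = [mk(f"frag {i} only") for i in range(7)]
        records = base + dups + frags
        assert len(records) == 100
        kept, report = preprocess(records)
        # independent brute-force scan
        seen, survivors = set(), 0
        for r in records:
            if r.tokens in seen:
                continue
            seen.add(r.tokens)
            if len(r.tokens) >= 5:
                survivors += 1
        assert survivors == 83
        assert len(kept) == 83
        assert report.n_duplicates_removed == 10
        assert report.n_short_removed == 7

    def test_min_tokens_validation(self, mk):
        with pytest.raises(ValidationError):
            preprocess([mk("a b c d e")], min_tokens=0)

    @given(st.lists(st.lists(st.sampled_from("abcdef"), min_size=1, max_size=8), max_size=30))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_idempotent(self, token_lists):
        records = [make_record(toks) for toks in token_lists]
        once, _ = preprocess(records)
        twice, report = preprocess(once)
        assert twice == once
        assert report.n_duplicates_removed == 0 and report.n_short_removed == 0


class TestBalanceDownsample:
    def test_full_scale_protocol_counts(self, mk):
        positives = [mk(f"pos sentence {i} a b", POSITIVE) for i in range(1451)]
        hard = [mk(f"hard negative {i} a b", NEGATIVE, negated=True) for i in range(285)]
        pool = [mk(f"pool negative {i} a b", NEGATIVE) for i in range(3000)]
        out = balance_downsample(positives, hard, pool, seed=11)
        assert len(out) == 2902
        n_sampled = len(out) - len(positives) - len(hard)
        assert n_sampled == 1166
        labels = [r.label for r in out]
        assert labels.count(POSITIVE) == labels.count(NEGATIVE) == 1451

    def test_no_sampling_needed(self, mk):
        positives = [mk(f"p {i} x y z", POSITIVE) for i in range(5)]
        hard = [mk(f"h {i} x y z", NEGATIVE, negated=True) for i in range(5)]
        out = balance_downsample(positives, hard, [], seed=0)
        assert len(out) == 10

    def test_deterministic_and_contains_all_hard_negatives(self, mk):
        positives = [mk(f"p {i}", POSITIVE) for i in range(8)]
        hard = [mk(f"h {i}", NEGATIVE, negated=True) for i in range(3)]
        pool = [mk(f"n {i}", NEGATIVE) for i in range(20)]
        out1 = balance_downsample(positives, hard, pool, seed=42)
        out2 = balance_downsample(positives, hard, pool, seed=42)
        assert [r.sentence_id for r in out1] == [r.sentence_id for r in out2]
        assert len(out1) - len(positives) - len(hard) == 5
        ids = {r.sentence_id for r in out1}
        assert all(h.sentence_id in ids for h in hard)

    def test_insufficient_pool_reports_shortfall(self, mk):
        positives = [mk(f"p {i}", POSITIVE) for i in range(10)]
        pool = [mk(f"n {i}", NEGATIVE) for i in range(4)]
        with pytest.raises(ValidationError, match="shortfall"):
            balance_downsample(positives, [], pool, seed=0)


class TestSplitTrainTest:
    def test_balanced_2902_split_size(self, mk):
        records = [mk(f"p {i}", POSITIVE) for i in range(1451)] + [
            mk(f"n {i}", NEGATIVE) for i in range(1451)
        ]
        split = split_train_test(records, test_fraction=0.1, seed=5)
        assert abs(len(split.test) - 290) <= 1
        assert len(split.train) + len(split.test) == 2902

    def test_exact_partition_and_stratification(self, mk):
        records = [mk(f"p {i}", POSITIVE) for i in range(30)] + [
            mk(f"n {i}", NEGATIVE) for i in range(70)
        ]
        split = split_train_test(records, test_fraction=0.2, seed=1)
        all_ids = {r.sentence_id for r in records}
        got = {r.sentence_id for r in split.train} | {r.sentence_id for r in split.test}
        assert got == all_ids
        test_pos = sum(r.label == POSITIVE for r in split.test)
        assert abs(test_pos - 6) <= 1
        assert abs((len(split.test) - test_pos) - 14) <= 1

    def test_seeds_change_membership_not_sizes(self, mk):
        records = [mk(f"p {i}", POSITIVE) for i in range(12)] + [
            mk(f"n {i}", NEGATIVE) for i in range(12)
        ]
        s1 = split_train_test(records, test_fraction=0.5, seed=1)
        s2 = split_train_test(records, test_fraction=0.5, seed=2)
        assert len(s1.test) == len(s2.test) == 12
        assert {r.sentence_id for r in s1.test} != {r.sentence_id for r in s2.test}

    def test_same_seed_identical(self, small_labeled_corpus):
        s1 = split_train_test(small_labeled_corpus, 0.2, seed=9)
        s2 = split_train_test(small_labeled_corpus, 0.2, seed=9)
        assert s1.train == s2.train and s1.test == s2.test

    def test_too_few_per_class(self, mk):
        with pytest.raises(ValidationError):
            split_train_test(
                [mk("a b", POSITIVE), mk("c d", NEGATIVE)], 0.5, seed=0
            )


class TestNegationSetting:
    def test_full_scale_setting_holds_out_100(self, mk):
        positives = [mk(f"p {i}", POSITIVE) for i in range(1451)]
        negated = [mk(f"g {i}", NEGATIVE, negated=True) for i in range(285)]
        split = make_negation_setting(positives, negated, n_train_neg=185, seed=4)
        assert len(split.test) == 100
        assert len(split.train) == 1451 + 185
        assert all(r.is_negated_bleeding for r in split.test)

    def test_small_arithmetic(self, mk):
        positives = [mk(f"p {i}", POSITIVE) for i in range(10)]
        negated = [mk(f"g {i}", NEGATIVE, negated=True) for i in range(4)]
        split = make_negation_setting(positives, negated, n_train_neg=3, seed=0)
        assert len(split.test) == 1

    def test_deterministic(self, mk):
        positives = [mk(f"p {i}", POSITIVE) for i in range(6)]
        negated = [mk(f"g {i}", NEGATIVE, negated=True) for i in range(5)]
        a = make_negation_setting(positives, negated, n_train_neg=2, seed=3)
        b = make_negation_setting(positives, negated, n_train_neg=2, seed=3)
        assert a.train == b.train and a.test == b.test

    def test_requires_spare_negated(self, mk):
        with pytest.raises(ValidationError):
            make_negation_setting(
                [make_record("p x", POSITIVE)],
                [make_record("g x", NEGATIVE, negated=True)],
                n_train_neg=1,
                seed=0,
            )
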