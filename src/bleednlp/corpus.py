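"""Corpus I/O, preprocessing filters, class balancing, and splits.

This module implements the data protocol used to build a balanced
sentence-classification corpus from an annotated note collection:

* deduplicate exact token sequences and drop fragments shorter than
  five tokens;
* balance by downsampling — keep every positive sentence, keep every
  negated-bleeding hard negative, and sample just enough additional
  negatives to reach a 50/50 class mix;
* hold out a random tenth of the balanced corpus for testing;
* optionally construct the "negation bleeding" setting, where the only
  negatives are the negated-bleeding hard negatives.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from ._rng import derive_rng
from .records import (
    NEGATIVE,
    POSITIVE,
    UNLABELED,
    CorpusSplit,
    SentenceRecord,
    ValidationError,
)

__all__ = [
    "tokenize",
    "read_corpus",
    "write_corpus",
    "preprocess",
    "PreprocessReport",
    "balance_downsample",
    "split_train_test",
    "make_negation_setting",
]

_TOKEN_RE = re.compile(r"[a-z0-9]+(?:[-'][a-z0-9]+)*|[^\sa-z0-9]")


def tokenize(text: str) -> list[str]:
    """Lowercase and split a sentence into word and punctuation tokens.

    Deterministic rule-based tokenization: words (keeping internal
    hyphens/apostrophes, e.g. "heme-positive") are separated from
    punctuation, which becomes its own token.

    >>> tokenize("No bleeding problems.")
    ['no', 'bleeding', 'problems', '.']
    """
    return _TOKEN_RE.findall(text.lower())


class CorpusParseError(ValueError):
    """A corpus file row could not be parsed; carries the line number."""

    def __init__(self, path: str | Path, line: int, message: str) -> None:
        super().__init__(f"{path}:{line}: {message}")
        self.line = line


def _record_from_row(row: dict, path, line: int, default_id: str) -> SentenceRecord:
    if "tokens" in row and row["tokens"]:
        tokens = row["tokens"]
        if isinstance(tokens, str):  # CSV cell: space-joined
            tokens = tokens.split()
        tokens = [str(t) for t in tokens]
    elif "text" in row and row["text"] is not None:
        tokens = tokenize(str(row["text"]))
    else:
        raise CorpusParseError(path, line, "row has neither 'tokens' nor 'text'")
    label = row.get("label") or UNLABELED
    if label not in (POSITIVE, NEGATIVE, UNLABELED):
        raise ValidationError(f"{path}:{line}: unknown label {label!r}")
    neg_flag = row.get("is_negated_bleeding", False)
    if isinstance(neg_flag, str):
        neg_flag = neg_flag.strip().lower() in ("true", "1", "yes")
    try:
        return SentenceRecord(
            note_id=str(row.get("note_id") or "n0"),
            sentence_id=str(row.get("sentence_id") or default_id),
            tokens=tuple(tokens),
            label=label,
            is_negated_bleeding=bool(neg_flag),
        )
    except ValidationError as exc:
        raise ValidationError(f"{path}:{line}: {exc}") from exc


def read_corpus(path: str | Path, format: str | None = None) -> list[SentenceRecord]:
    """Read sentence records from JSONL, CSV, or plain text.

    JSONL/CSV rows carry ``text`` or ``tokens``, ``label``, and the
    optional ``note_id``/``sentence_id``/``is_negated_bleeding`` fields.
    Plain text yields one unlabeled, whitespace-tokenized record per
    non-empty line. When `format` is None it is inferred from the suffix.
    """
    path = Path(path)
    if format is None:
        format = {".jsonl": "jsonl", ".json": "jsonl", ".csv": "csv"}.get(
            path.suffix.lower(), "plaintext"
        )
    records: list[SentenceRecord] = []
    if format == "jsonl":
        with path.open() as fh:
            for i, raw in enumerate(fh, start=1):
                raw = raw.strip()
                if not raw:
                    continue
                try:
                    row = json.loads(raw)
                except json.JSONDecodeError as exc:
                    raise CorpusParseError(path, i, f"invalid JSON: {exc.msg}") from exc
                records.append(_record_from_row(row, path, i, default_id=f"s{i:06d}"))
    elif format == "csv":
        with path.open(newline="") as fh:
            reader = csv.DictReader(fh)
            for i, row in enumerate(reader, start=2):  # header is line 1
                records.append(_record_from_row(row, path, i, default_id=f"s{i:06d}"))
    elif format == "plaintext":
        with path.open() as fh:
            for i, raw in enumerate(fh, start=1):
                raw = raw.strip()
                if not raw:
                    continue
                records.append(
                    SentenceRecord(
                        note_id="n0",
                        sentence_id=f"u{i:06d}",
                        tokens=tuple(raw.split()),
                        label=UNLABELED,
                    )
                )
    else:
        raise ValidationError(f"unknown corpus format {format!r}")
    return records


def write_corpus(records: Iterable[SentenceRecord], path: str | Path) -> None:
    """Write records as JSONL (one object per line, file order preserved)."""
    path = Path(path)
    with path.open("w") as fh:
        for r in records:
            fh.write(
                json.dumps(
                    {
                        "note_id": r.note_id,
                        "sentence_id": r.sentence_id,
                        "tokens": list(r.tokens),
                        "label": r.label,
                        "is_negated_bleeding": r.is_negated_bleeding,
                    }
                )
                + "\n"
            )


@dataclass(frozen=True)
class PreprocessReport:
    n_input: int
    n_duplicates_removed: int
    n_short_removed: int

    @property
    def n_kept(self) -> int:
        return self.n_input - self.n_duplicates_removed - self.n_short_removed


def preprocess(
    records: Sequence[SentenceRecord], min_tokens: int = 5
) -> tuple[list[SentenceRecord], PreprocessReport]:
    """Collapse exact duplicate token sequences and drop short fragments.

    Duplicates (identical token tuples) keep only their first occurrence;
    sentences with fewer than `min_tokens` tokens are removed. Relative
    order is preserved. Idempotent. Returns the surviving records and a
    count report.
    """
    if min_tokens < 1:
        raise ValidationError(f"min_tokens must be >= 1, got {min_tokens}")
    seen: set[tuple[str, ...]] = set()
    kept: list[SentenceRecord] = []
    n_dup = n_short = 0
    for r in records:
        if r.tokens in seen:
            n_dup += 1
            continue
        seen.add(r.tokens)
        if len(r.tokens) < min_tokens:
            n_short += 1
            continue
        kept.append(r)
    return kept, PreprocessReport(len(records), n_dup, n_short)


def balance_downsample(
    positives: Sequence[SentenceRecord],
    hard_negatives: Sequence[SentenceRecord],
    negative_pool: Sequence[SentenceRecord],
    seed: int,
) -> list[SentenceRecord]:
    """Build a 50/50 corpus: all positives, all hard negatives, sampled rest.

    Keeps every positive sentence and every negated-bleeding hard
    negative, then samples exactly ``len(positives) - len(hard_negatives)``
    additional negatives uniformly without replacement from
    `negative_pool`. With 1451 positives and 285 hard negatives this
    samples 1166 negatives for a balanced corpus of 2902 sentences.
    """
    n_needed = len(positives) - len(hard_negatives)
    if n_needed < 0:
        raise ValidationError(
            f"more hard negatives ({len(hard_negatives)}) than positives "
            f"({len(positives)})"
        )
    if len(negative_pool) < n_needed:
        raise ValidationError(
            f"negative pool has {len(negative_pool)} records; "
            f"{n_needed} needed (shortfall {n_needed - len(negative_pool)})"
        )
    ids = [
        r.sentence_id
        for group in (positives, hard_negatives, negative_pool)
        for r in group
    ]
    if len(ids) != len(set(ids)):
        raise ValidationError("positive/hard-negative/pool records overlap by sentence_id")

    rng = derive_rng(seed, "balance_downsample")
    chosen = rng.choice(len(negative_pool), size=n_needed, replace=False)
    sampled = [negative_pool[i] for i in sorted(chosen)]
    out = (
        [r.with_label(POSITIVE) for r in positives]
        + [r.with_label(NEGATIVE, is_negated_bleeding=True) for r in hard_negatives]
        + [r.with_label(NEGATIVE) for r in sampled]
    )
    return out


def split_train_test(
    records: Sequence[SentenceRecord],
    test_fraction: float = 0.1,
    seed: int = 0,
    stratify: bool = True,
) -> CorpusSplit:
    """Randomly hold out `test_fraction` of the records (default 1 in 10).

    Assignment is uniform without replacement and, by default, stratified
    by label so each class contributes `test_fraction` of its records
    within one. Deterministic given `seed`; exact partition of the input.
    """
    if not records:
        raise ValidationError("cannot split an empty corpus")
    if not 0.0 < test_fraction < 1.0:
        raise ValidationError(f"test_fraction must be in (0,1), got {test_fraction}")
    rng = derive_rng(seed, "split_train_test")
    test_idx: set[int] = set()
    if stratify:
        by_label: dict[str, list[int]] = {}
        for i, r in enumerate(records):
            by_label.setdefault(r.label, []).append(i)
        for label, idxs in sorted(by_label.items()):
            if len(idxs) < 2:
                raise ValidationError(
                    f"class {label!r} has {len(idxs)} record(s); "
                    "at least 2 are required for a stratified split"
                )
            n_test = int(round(test_fraction * len(idxs)))
            n_test = min(max(n_test, 1), len(idxs) - 1)
            chosen = rng.choice(len(idxs), size=n_test, replace=False)
            test_idx.update(idxs[i] for i in chosen)
    else:
        n_test = int(round(test_fraction * len(records)))
        n_test = min(max(n_test, 1), len(records) - 1)
        test_idx.update(rng.choice(len(records), size=n_test, replace=False).tolist())
    train = [r for i, r in enumerate(records) if i not in test_idx]
    test = [r for i, r in enumerate(records) if i in test_idx]
    return CorpusSplit(
        train=tuple(train), test=tuple(test), split_seed=seed, test_fraction=test_fraction
    )


def make_negation_setting(
    positives: Sequence[SentenceRecord],
    negated: Sequence[SentenceRecord],
    n_train_neg: int = 185,
    seed: int = 0,
) -> CorpusSplit:
    """Build the negation-bleeding setting: hard negatives only.

    Training data are all positives plus `n_train_neg` sampled
    negated-bleeding sentences; the remaining negated sentences form the
    test set (285 negated sentences with 185 in training leave a test set
    of 100). The test set therefore contains only negatives, and models
    are scored on negative-class accuracy.
    """
    if n_train_neg >= len(negated):
        raise ValidationError(
            f"n_train_neg ({n_train_neg}) must be < number of negated "
            f"sentences ({len(negated)})"
        )
    rng = derive_rng(seed, "make_negation_setting")
    chosen = set(rng.choice(len(negated), size=n_train_neg, replace=False).tolist())
    train_neg = [negated[i] for i in sorted(chosen)]
    test_neg = [r for i, r in enumerate(negated) if i not in chosen]
    train = [r.with_label(POSITIVE) for r in positives] + [
        r.with_label(NEGATIVE, is_negated_bleeding=True) for r in train_neg
    ]
    test = [r.with_label(NEGATIVE, is_negated_bleeding=True) for r in test_neg]
    return CorpusSplit(
        train=tuple(train),
        test=tuple(test),
        split_seed=seed,
        test_fraction=len(test) / (len(train) + len(test)),
    )
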