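"""Core record types shared by every pipeline stage.

A corpus is a list of :class:`SentenceRecord` objects — one tokenized
sentence each, carrying its binary bleeding label, an optional
negated-bleeding flag (a hard negative: bleeding vocabulary under a
negation cue), and the identifier of the note it came from.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

POSITIVE = "positive"
NEGATIVE = "negative"
UNLABELED = "unlabeled"
LABELS = (POSITIVE, NEGATIVE, UNLABELED)


class ValidationError(ValueError):
    """A record, configuration, or argument violates a documented contract."""


@dataclass(frozen=True)
class SentenceRecord:
    """One tokenized clinical sentence.

    Parameters
    ----------
    note_id : str
        Opaque identifier of the source note.
    sentence_id : str
        Identifier unique within a corpus.
    tokens : tuple of str
        Word tokens, in order; never empty.
    label : str
        ``"positive"`` (contains a bleeding event), ``"negative"``, or
        ``"unlabeled"``.
    is_negated_bleeding : bool
        True only for negative sentences that mention bleeding vocabulary
        under a negation cue ("no bleeding problems") — the hard negatives.
    """

    note_id: str
    sentence_id: str
    tokens: tuple[str, ...]
    label: str = UNLABELED
    is_negated_bleeding: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", tuple(self.tokens))
        if not self.tokens:
            raise ValidationError(
                f"sentence {self.sentence_id!r}: tokens must be non-empty"
            )
        if self.label not in LABELS:
            raise ValidationError(
                f"sentence {self.sentence_id!r}: unknown label {self.label!r}"
            )
        if self.is_negated_bleeding and self.label != NEGATIVE:
            raise ValidationError(
                f"sentence {self.sentence_id!r}: is_negated_bleeding requires "
                f"label 'negative', got {self.label!r}"
            )

    @property
    def text(self) -> str:
        return " ".join(self.tokens)

    def with_label(self, label: str, is_negated_bleeding: bool = False) -> "SentenceRecord":
        return replace(self, label=label, is_negated_bleeding=is_negated_bleeding)


def check_unique_ids(records: Iterable[SentenceRecord]) -> None:
    """Raise :class:`ValidationError` if any sentence_id repeats."""
    seen: set[str] = set()
    for r in records:
        if r.sentence_id in seen:
            raise ValidationError(f"duplicate sentence_id {r.sentence_id!r}")
        seen.add(r.sentence_id)


@dataclass(frozen=True)
class CorpusSplit:
    """A train/test partition of a corpus, disjoint by sentence_id."""

    train: tuple[SentenceRecord, ...]
    test: tuple[SentenceRecord, ...]
    split_seed: int = 0
    test_fraction: float = 0.1

    def __post_init__(self) -> None:
        object.__setattr__(self, "train", tuple(self.train))
        object.__setattr__(self, "test", tuple(self.test))
        train_ids = {r.sentence_id for r in self.train}
        test_ids = {r.sentence_id for r in self.test}
        if train_ids & test_ids:
            raise ValidationError("train and test overlap by sentence_id")


def label_counts(records: Sequence[SentenceRecord]) -> dict[str, int]:
    counts = {lab: 0 for lab in LABELS}
    for r in records:
        counts[r.label] += 1
    return counts
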