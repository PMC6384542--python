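import numpy as np
import pytest

from bleednlp.records import NEGATIVE, POSITIVE, SentenceRecord


def make_record(
    tokens,
    label=NEGATIVE,
    sentence_id=None,
    note_id="n0",
    negated=False,
    _counter=[0],
):
    if sentence_id is None:
        _counter[0] += 1
        sentence_id = f"fx{_counter[0]:06d}"
    if isinstance(tokens, str):
        tokens = tokens.split()
    return SentenceRecord(
        note_id=note_id,
        sentence_id=sentence_id,
        tokens=tuple(tokens),
        label=label,
        is_negated_bleeding=negated,
    )


@pytest.fixture
def mk():
    return make_record


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_labeled_corpus(mk):
    """Ten distinct labeled sentences, five per class."""
    pos = [
        mk(f"patient admitted with hematemesis episode {i}", POSITIVE)
        for i in range(5)
    ]
    neg = [
        mk(f"follow up with cardiology clinic visit {i}", NEGATIVE) for i in range(5)
    ]
    return pos + neg
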