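"""Generate a synthetic clinical-sentence corpus and preprocess it.

Builds a seeded corpus of template-generated sentences — affirmative
bleeding mentions, negated-bleeding hard negatives, and distractors —
then applies the two preprocessing filters: exact-duplicate removal
and the <5-token fragment filter.
"""

from bleednlp import GeneratorConfig, generate_corpus, preprocess

config = GeneratorConfig(
    n_notes=20,
    sentences_per_note=(30, 50),
    positive_prevalence=0.029,  # real-corpus-like prevalence
    negated_fraction_of_bleeding_mentions=0.164,  # 285 : 1451
    fragment_rate=0.05,
    duplicate_rate=0.03,
    seed=42,
)

raw = generate_corpus(config)
kept, report = preprocess(raw, min_tokens=5)

n_pos = sum(r.label == "positive" for r in kept)
n_hard = sum(r.is_negated_bleeding for r in kept)
print(f"generated      : {report.n_input} sentences in {config.n_notes} notes")
print(f"duplicates     : {report.n_duplicates_removed} removed")
print(f"fragments (<5) : {report.n_short_removed} removed")
print(f"kept           : {report.n_kept}")
print(f"positives      : {n_pos} ({n_pos / report.n_kept:.1%} prevalence)")
print(f"hard negatives : {n_hard} (negated bleeding mentions)")
print()
print("example positive     :", next(r.text for r in kept if r.label == "positive"))
print("example hard negative:", next(r.text for r in kept if r.is_negated_bleeding))
# The prevalence mirrors a real annotated note collection: bleeding
# events are rare, and a slice of bleeding-mentioning sentences are
# negated -- the hard negatives a keyword matcher gets wrong.
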