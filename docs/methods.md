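# Methods

This note records the model, the data protocol, the synthetic-data design,
and the numerical and design choices behind `bleednlp`, in enough detail to
reproduce or modify any of them.

## Task and model

The task is binary sentence classification: does a clinical note sentence
describe a bleeding event? The classifier fuses two sentence
representations computed in parallel.

**Convolutional path.** A sentence of `n` tokens is embedded into an
`n × d` matrix (`d` = 200 by default). For each filter width `k` in
{3, 4, 5}, a bank of 10 filters computes
`c_i = tanh(w · [e_i; …; e_{i+k−1}] + b)` at every position; sentences
shorter than `k` are zero-padded so every filter sees at least one window
(padding contributes zero rows; partial windows are not masked).
Max-over-time pooling keeps one value per filter. The pooled vector has
length `10 × 3 = 30`. The count "10 filters" is implemented as 10 *per
width*: per-width banks are the convention for multi-width text CNNs, and
a total of 10 does not divide evenly into three widths. Both the widths
and the per-width count are configurable.

**Recurrent path.** A sequence autoencoder is pretrained on unlabeled
sentences. The encoder is an LSTM with hidden size `k` = 64 that scans the
sentence forward and then backward; by default the two directions *share
one set of weights* (a single LSTM reading the sentence twice, the second
time reversed), with `shared_direction_weights=false` switching to the
conventional separate-weights BiLSTM. The sentence representation is the
concatenation of the two final hidden states, `h ∈ R^{2k}` (128 by
default). The decoder is a separate unidirectional LSTM of width `k`: its
initial hidden and cell states are learned linear projections of the
2k-vector (the minimal learnable adapter between the 2k encoder output and
the k-wide decoder; no tying between the output layer, the encoder, or the
embedding matrix). During training the decoder consumes the embedding of
the *previous target token* (teacher forcing), starting from a BOS symbol,
and an affine layer plus softmax over the vocabulary scores each step
against the input sequence terminated by EOS; the loss is mean token-level
cross-entropy, masked over padding. With teacher forcing disabled the
decoder feeds back its own greedy prediction. BOS/EOS exist only for the
decoder; the convolutional path never sees them. The output layer is
initialized near zero so an untrained model is near-uniform over the
vocabulary and its per-token loss sits at `ln |V|` — a useful calibration
check.

**Fusion and output.** The pooled CNN features and the 2k representation
are concatenated, dropout (rate 0.3) is applied to the concatenated vector
(the rate is a fixed default; applying it to the features rather than the
embeddings is our choice), and a fully connected layer plus softmax
produces `P(bleeding)`. Probabilities at or above the 0.5 cutoff predict
positive; the tie at exactly 0.5 resolves to positive, the recall-favoring
choice for safety surveillance (configurable). By default the pretrained
encoder is *frozen* during classifier training and acts as a feature
extractor; `freeze_encoder=false` enables joint fine-tuning. With fusion
disabled the forward pass is exactly the standalone CNN classifier.

**Variants.** Seven named configurations: `cnn` / `cnn_pre` (CNN with
random / file-loaded word vectors), `ae_clf` / `ae_clf_pre` (encoder
representation + fully connected softmax), `hcla` (the hybrid), and
`cnn_neg` / `hcla_neg` (the same architectures under the negation-bleeding
data setting). For `ae_clf` either a reconstruction-pretrained or a
supervised encoder would be defensible; we train
embedding + encoder + head end-to-end on the labels (with optional
autoencoder initialization when a pool is supplied), which is the stronger
and more standard reading of "a fully connected layer on the hidden
representation". Pretrained word vectors load from GloVe/word2vec text
format and are fine-tuned by default (`freeze_embeddings` disables this).

## Optimization

Plain SGD with optional global gradient-norm clipping (default 5.0).
Default hyperparameters: learning rate 0.001, batch 16, dropout 0.3,
`d` = 200, `k` = 64. Epoch count and model selection are genuinely open
choices, so the trainer defaults to 30 epochs with best-epoch
selection on a stratified 10% validation carve-out of the training data
(ties on validation accuracy break toward the epoch with lower training
loss). Batches pad to the longest sentence (floored at the widest filter);
the recurrent scans freeze state across padded steps and pooled
convolution positions beyond a sentence's own windows are masked, so
predictions are batch-size independent (asserted to 1e−6 in tests). The
PAD embedding row is pinned to zero by masking its gradient. All tensors
are float64; all randomness flows through named streams derived from the
user seed (one stream per operation), so results do not depend on call
order and identical configurations reproduce reports byte-for-byte in
single-threaded mode.

On the small synthetic benchmarks used in the test suite the default
learning rate of 0.001 is needlessly slow; the tests and example scripts
train at 0.05 (classifiers) and 0.5–1.5 (autoencoder memorization), which
changes nothing about the architecture. The autoencoder pretraining
default is 5 epochs; the memorization check uses 600 epochs on 20
sentences because its purpose is capacity, not generalization.

## Data protocol

Preprocessing collapses exact duplicate token sequences (first occurrence
wins, comparison on tokens after lowercasing/punctuation-splitting — the
tokenizer is pluggable since token counts, not a specific tokenizer, are
what the protocol fixes) and removes sentences shorter than 5 tokens; the
operation is idempotent and reports its removal counts. Balancing keeps
every positive and every negated-bleeding hard negative and samples
exactly `|positives| − |hard negatives|` further negatives uniformly
without replacement, yielding a corpus with exactly 50% positives (1451 and
285 give 1166 sampled and 2902 total). The train/test split holds out a
random tenth, stratified by label (stratification preserves the 50/50
design in both partitions at small n; an unstratified mode is a flag since
a plain "1 of 10" draw is equally defensible). The
negation-bleeding setting trains on all positives plus 185 sampled
negated sentences and tests on the remaining 100 negated sentences; its
test set is all-negative, so models are scored by negative-class accuracy
and AUC is undefined (reported as absent). A leakage guard refuses to
pretrain the autoencoder on any sentence whose id appears in the test
split.

## Evaluation

Per-class precision, recall and F1 come from the confusion counts, with
the zero-denominator convention P = R = F = 0 plus a warning. "Overall" is
micro-averaging, under which precision = recall = F = accuracy for
single-label binary data — the reason report tables show three identical
overall columns; macro-averaging is a flag. AUC-ROC uses the exact
tie-aware Mann–Whitney rank formulation (ties count one half), computed
from average ranks; it is checked in tests against exhaustive
positive–negative pair comparison and against scikit-learn's
implementation, and is invariant under strictly monotone score transforms.

## Synthetic data

The generator emulates the *structure* of an annotated EHR note corpus,
not clinical language. Sentences come from template grammars over closed
lexicons: affirmative bleeding frames (positive), negated-bleeding frames
(hard negatives, with the cue either adjacent to the bleeding term or
separated from it by a symptom list longer than the widest filter), and
bleeding-free distractor frames. Defaults mirror the corpus the protocol
was designed around: positive prevalence 0.029, negated fraction of
bleeding mentions 0.164 (≈ 285/1736), with short fragments (5%) and
explicit duplicates (3%) planted to exercise preprocessing. Because
templates have bounded entropy, the generator also produces *incidental*
duplicates beyond the configured rate — more than a real note corpus
would — so deduplicated synthetic corpora are smaller than their raw
counts; tests size their corpora after preprocessing. The benchmark
corpora used in tests raise prevalence (0.18–0.5) so that desk-scale
corpora contain enough positives; the ratios, not the absolute counts, are
what carry over from the real protocol.

What passing tests show: the implementation learns, the protocol counts
are exact, the hybrid's fusion does not hurt under long-range negation,
and every numerical kernel matches an independent oracle. What they do not
show: performance on real clinical text, whose vocabulary, negation
variety, misspellings and discourse structure the templates do not model.
The non-inferiority check (hybrid vs CNN under long-range negation) is
stochastic and is evaluated on the mean held-out F1 over 5 seeds.

## Degenerate inputs and edge rules

Empty sequences are rejected for encoding/decoding; one-token sentences
are valid everywhere (single recurrence step; zero-padded convolution
window). Empty corpora are rejected where an operation would be undefined
(vocabulary building, splitting) and pass through harmlessly elsewhere
(prediction on an empty record list returns empty outputs). Probability
exactly at the cutoff is positive. Non-finite losses abort training with
the epoch number. Checkpoints store a vocabulary hash and refuse to load
against a different vocabulary.

## Known limitations

- Pure-NumPy training is practical only at desk scale (thousands of
  sentences); the design favors auditability and determinism over speed.
- The generator's closed lexicons make bag-of-words nearly sufficient;
  real negation detection is much harder than the synthetic benchmark.
- Note-level context, section structure, and assertion status (current vs
  historical bleeding) are out of scope: the unit of classification is the
  sentence.
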