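"""Pretrain the BiLSTM sequence autoencoder on unlabeled sentences.

The encoder reads each sentence forward and backward; the concatenated
final hidden states (a 2k vector) become the sentence representation.
The decoder reconstructs the sentence token by token from that vector,
so falling reconstruction loss means the representation is absorbing
the sentence's content.
"""

import numpy as np

from bleednlp import (
    AutoencoderConfig,
    BiLSTMAutoencoder,
    GeneratorConfig,
    build_vocab,
    generate_unlabeled_pool,
    init_embeddings,
    pretrain,
)

gen = GeneratorConfig(n_notes=10, positive_prevalence=0.2, seed=11)
pool = generate_unlabeled_pool(gen, 60)
vocab = build_vocab(pool)
print(f"pool: {len(pool)} unlabeled sentences, vocabulary of {len(vocab)} tokens")

config = AutoencoderConfig(
    hidden_size=48, embedding_dim=64, epochs=250, learning_rate=1.0, seed=11
)
model = BiLSTMAutoencoder(vocab, init_embeddings(vocab, 64, seed=11), config)

first = pool[0]
encoded = vocab.encode(first.tokens)
print(f"untrained loss : {model.reconstruction_loss(encoded):.3f} "
      f"(ln |V| = {np.log(len(vocab)):.3f})")

history = pretrain(model, pool, config)
print(f"trained loss   : epoch 1 = {history[0]:.3f} -> epoch {len(history)} = {history[-1]:.3f}")

rep = model.encode(encoded)
print(f"representation : length {len(rep.vector)} (= 2 x {config.hidden_size})")
print("input          :", first.text)
print("reconstruction :", " ".join(vocab.decode(model.greedy_decode(encoded))))
# An untrained decoder is uniform over the vocabulary (loss = ln |V|);
# training pushes the loss down and the greedy reconstruction toward
# the input, so the 2k vector summarizes the whole sentence.
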