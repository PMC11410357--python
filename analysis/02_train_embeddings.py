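#!/usr/bin/env python
"""Train skip-gram segment vectors end to end on a toy corpus.

Builds a synthetic sentence corpus over the stimulus vocabulary (same-cluster
words share contexts), segments it with the ground-truth lexicon, trains the
internal skip-gram model, and composes word vectors by summation.  Reports
how well the trained space separates semantic clusters, and repeats the run
in the out-of-vocabulary regime (no sentence contains a stimulus word).
"""

import dataclasses
from pathlib import Path

import numpy as np

from subdecode.embedding import EmbeddingConfig, compose_word_vectors, cosine_distance, write_vectors
from subdecode.experiments import DISSOCIATION_CONFIG
from subdecode.segmentation import load_segmentation_lexicon
from subdecode.synthetic import generate_corpus, make_dataset

SEED = 1

out = Path("results")
out.mkdir(exist_ok=True)
config = dataclasses.replace(DISSOCIATION_CONFIG, seed=SEED)
_, truth = make_dataset(config)
lexicon = truth.lexicon

emb = EmbeddingConfig(dim=config.dim, context_window=7, min_count=50, epochs=5, seed=SEED)


def cluster_separation(wordvecs):
    within, between = [], []
    for i, wi in enumerate(wordvecs.words):
        ci = truth.stem_cluster[lexicon.segments_of(wi)[0]]
        for wj in wordvecs.words[i + 1:]:
            cj = truth.stem_cluster[lexicon.segments_of(wj)[0]]
            d = cosine_distance(wordvecs.matrix[wordvecs.words.index(wi)],
                                wordvecs.matrix[wordvecs.words.index(wj)])
            (within if ci == cj else between).append(d)
    return float(np.mean(within)), float(np.mean(between))


from subdecode.embedding import train_segment_vectors

for regime, exclude in (("standard", False), ("oov", True)):
    sentences = generate_corpus(lexicon, config, min_frequency=50,
                                exclude_targets=exclude, stem_cluster=truth.stem_cluster)
    store = train_segment_vectors(sentences, emb, scheme=lexicon.scheme, lexicon=lexicon)
    wv = compose_word_vectors(lexicon, store, truth.words)
    covered = [w for w in truth.words if w not in wv.uncovered_words]
    w_mean, b_mean = cluster_separation(wv.select(covered))
    write_vectors(store, out / f"segments_trained_{regime}.vec")
    print(f"[{regime}] {len(sentences)} sentences, {len(store)} segment vectors, "
          f"{len(covered)}/{len(truth.words)} words covered")
    print(f"[{regime}] mean cosine distance within clusters {w_mean:.3f} "
          f"vs between clusters {b_mean:.3f}")
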