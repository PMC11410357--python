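# subdecode

Decoding evoked MEG responses to morphologically complex written words with
**compositional subword embeddings**, and telling apart two very different
reasons such decoding can succeed.

## The problem

In agglutinative languages such as Finnish, most word forms are
multimorphemic (e.g. *talo+j+en*, "of the houses") and individually rare, so
reliable whole-word distributional vectors often cannot be estimated from
any corpus.  A way out is to segment words into subword units (linguistic
morphemes, statistical morphs, character n-grams, or random chunks), train a
skip-gram model on the segmented corpus, and represent each word as the
**sum of its segment vectors**, `v_w = Σ_s v_s`.  These composed vectors can
then be decoded from item-averaged evoked sensor data: a ridge regression
`f: X → Y` maps windowed MEG features to the word-vector space, and decoding
accuracy is measured with the leave-two-out **2-vs-2 test** — a held-out
pair (w₁, w₂) counts as correct when

```
d(p1, a1) + d(p2, a2)  <  d(p1, a2) + d(p2, a1)
```

with `p` the predicted and `a` the actual vectors and `d` cosine distance.

The catch: summation composition makes words that *share segments* point in
similar directions regardless of what the individual segment vectors mean.
Shared-suffix structure alone can therefore support above-chance decoding.
The package's central statistic is the **segment-label permutation test**:
shuffle the bijection between segment labels and segment vectors, recompose
every word vector, and re-run the whole evaluation.  This null preserves the
segment-sharing pattern while destroying segment identity, so

* accuracy above the ordinary **word-label** threshold but *below* the
  segment-label threshold ⇒ decoding rides on shared-segment structure;
* accuracy above *both* thresholds ⇒ the segment vectors themselves carry
  decodable (semantic) information.

## What is in the box

| module | contents |
|---|---|
| `subdecode.segmentation` | whole-word / n-gram / random / external-lexicon segmentation, lexicon TSV IO, statistical-vs-linguistic comparison categories |
| `subdecode.embedding` | minimal NumPy skip-gram trainer, summation composition, cosine utilities, complete-linkage clustering + Newick export, word2vec text IO |
| `subdecode.decoding` | epochs container (HDF5/CSV), baseline & amplitude rejection, 100-ms/50-ms sliding windows, ridge with per-target-dimension alpha from a 100-point 1e-5..1e5 grid |
| `subdecode.evaluation` | 2-vs-2 test, cached leave-two-out engine, accuracy time courses |
| `subdecode.permutation` | word-label and segment-label nulls, 95th-percentile thresholds, empirical p-values |
| `subdecode.synthetic` | synthetic multimorphemic lexicon, structured segment vectors, toy corpus, simulated evoked responses |
| `subdecode.experiments` | the reference desk-scale study runs used by `analysis/` and the acceptance script |

`analysis/01…05` are thin numbered drivers that run the study end to end and
write tables under `results/`.  A `subdecode` CLI (`simulate`, `segment`,
`compare-seg`, `embed`, `compose`, `decode`, `permute`, `report`) wraps the
same functions for shell use.

## Worked example

```python
import dataclasses
from subdecode.decoding import apply_baseline
from subdecode.evaluation import run_two_vs_two
from subdecode.permutation import segment_label_null, word_label_null
from subdecode.experiments import DISSOCIATION_CONFIG
from subdecode.synthetic import make_dataset

config = dataclasses.replace(DISSOCIATION_CONFIG, seed=1)   # 40 words, SNR 5
epochs, truth = make_dataset(config)
ep = apply_baseline(epochs)

res = run_two_vs_two(ep, truth.wordvecs, max_pairs=500, seed=1)
wl = word_label_null(ep, truth.wordvecs, n_perm=100, seed=1, max_pairs=500)
sl = segment_label_null(ep, truth.lexicon, truth.store,
                        n_perm=100, seed=1, max_pairs=500)
print(wl.observed, wl.threshold, sl.threshold)
```

prints `0.922 0.6385 0.7521`: at the 400-ms window the true morphological
segmentation decodes at 0.922, above both the word-label threshold (0.64)
and the segment-label threshold (0.75) — the segment vectors carry real
information.  Running `analysis/04_permutation_tests.py` adds the two
control runs:

```
     run  observed_accuracy  word_label_threshold  segment_label_threshold  clears_word_label  clears_segment_label
   morph             0.9220                0.6385                   0.7521               True                  True
  random             0.4980                0.6281                   0.6061              False                 False
 unigram             0.7280                0.6782                   0.7940               True                 False
```

Random segmentation with meaningless vectors decodes at chance; character
1-grams decode *above the word-label threshold* (0.728 > 0.678) yet below
their segment-label threshold (0.794) — the textbook case of decoding driven
purely by shared-segment structure.  `analysis/03_decode_timecourse.py`
shows the time course: chance before stimulus onset, a sharp peak (0.926) in
the 350–500 ms effect window.  `analysis/05_type1_calibration.py` checks the
word-label test itself: 7.0% rejections at the nominal 5% level over 200
null replicates (SE 1.8%).

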