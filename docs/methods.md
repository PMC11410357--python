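# Methods

## Model and procedure

The analysis treats decoding as a windowed linear regression problem.  Let
`Y` be the `n_words × D` matrix of composed word vectors and `X` the
`n_words × (n_sensors · window_samples)` matrix of flattened sensor features
for one time window (sensor-major layout: all samples of sensor 0, then
sensor 1, …).  For every unordered pair of words the decoder is fitted on
the remaining `n − 2` words and both held-out responses are projected into
the vector space; the pair scores 1 when the matched cosine-distance sum
beats the crossed sum, 0 when it loses, and 0.5 on an exact tie.  Window
accuracy is the mean outcome over pairs.  Windows are 100 ms long and
advance by 50 ms, starting at the first epoch sample, so a −200…800 ms
epoch yields 19 windows; the pre-stimulus windows act as an internal
negative control.

**Ridge fit.**  Columns of `X` and `Y` are z-transformed using training rows
only (constant columns get unit scale with a warning), and a separate
regularization strength is selected per target dimension from 100
log-spaced values between 1e-5 and 1e5 (endpoints inclusive).  Selection
uses the exact leave-one-out identity `e_loo = e / (1 − h)` evaluated
through the SVD of the standardized training block, which makes the search
over all 100 × D (alpha, dimension) combinations a handful of matrix
products; an explicit leave-two-out search over the training rows is
available (`alpha_cv="l2o"`) and agrees on well-conditioned problems.
Predictions are de-standardized back to the original target scale before
the cosine comparison.  Two scope options exist: `per-fold` (default)
re-tunes inside every leave-two-out fold; `per-window` tunes once per
window on all words.  A `zscore="global"` mode standardizes over all words
at once, for comparison with analyses that z-transform before
cross-validation; it is not the default because it leaks held-out rows into
the scaling.

**Permutation nulls.**  The word-label null shuffles the assignment between
brain-response rows and word-vector rows with a uniform permutation and
re-runs the full evaluation; one permutation is drawn per null sample and
applied across all windows, so null time courses inherit the temporal
structure of a single mislabelling.  The segment-label null draws a uniform
bijection (identity allowed) over the segment *types of the stimulus words
under study*, reattaches the vectors, recomposes every word vector by
summation, and re-runs the evaluation.  Because composition is linear, the
recomposition is implemented as `C · S[perm]` with `C` the words × segments
occurrence-count matrix, which is exactly the sum-of-permuted-vectors
definition.  Thresholds are the 95th percentile of the null
(linear-interpolation quantile by default, nearest-rank by flag); the
empirical p-value is `(1 + #{null ≥ observed}) / (1 + n_perm)`.  Inside the
permutations the per-fold regularization strengths are fixed to the
observed run's values by default (fast mode); re-tuning per permutation is
available and is the faithful-but-slow option.  No correction across
windows is applied: per-window accuracies are compared against per-window
thresholds, and this is documented behavior rather than an oversight.

**Segment vectors.**  The skip-gram trainer is a compact NumPy
implementation of the standard objective: for each center segment, context
segments within a symmetric window are positive targets and `negative`
(default 5) samples per positive are drawn from the unigram^0.75
distribution; the learning rate decays linearly from 0.025 to 1e-4 over
`epochs` (default 5) passes.  Defaults for the structural hyperparameters
are dimension 300, context window 7, and a minimum segment frequency of 50
(segments below it receive no vector; words none of whose segments are
covered are flagged and excluded from decoder training rather than silently
zeroed).  Subsampling of frequent tokens is deliberately omitted — the toy
corpora the trainer targets have nearly flat frequency distributions.  The
trainer is validated against the distributional property that segments
sharing contexts end up close under cosine distance, not against any
specific reference vectors.

## Synthetic data: what it emulates and what it does not

The generator produces the structure the analysis assumes, at desk scale:

* **Lexicon** — words are `stem + 1–2 suffixes` over a closed suffix set
  (stems 4–8 characters, suffixes 1–3, echoing stimulus word lengths of
  6–15).  Every suffix is shared by many words and every stem is rare: the
  configuration that makes the segment-label test informative.
* **Segment vectors** — stems are isotropic noise around one of
  `semantic_clusters` centroids in the leading coordinates; suffixes occupy
  the complementary trailing coordinates with smaller norm (suffix scale
  2.5 vs cluster scale 3.0), hence are exactly orthogonal to stem
  centroids.  This mimics the semantic/grammatical split a distributional
  model learns without training one.
* **Evoked responses** — `data = envelope(t) · (A v_w)(s) · gain + ε` with
  `A` a random sensor-mixing matrix, a raised-cosine envelope supported
  exactly on the 350–500 ms effect window (so baseline windows are
  signal-free by construction), and standard Gaussian white noise.  SNR is
  defined as signal RMS over the envelope's support divided by noise RMS,
  averaged across sensors; the gain is solved from that definition, so
  SNR 0 is pure noise.  An AR(1) flag adds temporal noise correlation for
  robustness checks.

Passing tests on these data show that the pipeline recovers a planted
linear code and that the two nulls separate segment identity from shared
structure.  They do **not** show anything about real MEG: there is no
forward-model geometry, no colored or spatially correlated noise by
default, no inter-item variability in response latency, and the true
word-vector space is exactly the space being decoded, which inflates
accuracies relative to any real corpus model.

## Reference study conditions

`experiments.DISSOCIATION_CONFIG`: 40 words (20 stems × 2 suffixes), D=20,
4 semantic clusters, 6 sensors at 100 Hz (60 features per 100-ms window),
epoch −200…800 ms → 19 windows, SNR 5, 100 permutations per null, ≤500
subsampled pairs, thresholds compared at the 400-ms window.  The sensor
count and sampling rate are scaled down from the recording geometry the
defaults in `SyntheticConfig` mirror (204 gradiometers, 1000 Hz) to keep
the full three-run experiment with both nulls in the minutes range on one
CPU; the dissociation pattern does not depend on this scaling, only the
absolute accuracies do.  `experiments.CALIBRATION_CONFIG` (type-I check):
16 words, D=8, 10 sensors, SNR 0, 200 replicates × 100 permutations; the
binomial SE of the rejection-rate estimate is ≈1.5%, adequate for a 5%
nominal level.

## Numerical choices and edge cases

* n-gram chunking is contiguous, non-overlapping, left-to-right, final
  chunk possibly short; FastText-style overlapping n-grams are out of scope.
* The random scheme draws the segment count from the discrete uniform
  `{2, …, floor(l/2)}` and the split points uniformly without replacement
  from the `l − 1` interior boundaries; words of length ≤ 3 are left whole,
  lengths 4–5 force two segments.  Segmentation is cached per word type,
  so repeated tokens are split identically.
* Strings are sequences of Unicode code points; lengths are code-point
  counts (ä/ö count as one).
* Comparison categories for a statistical vs linguistic segmentation:
  `identical`, `unsegmented` (statistical left whole), `incomplete`
  (statistical boundaries a strict subset — morphs joined, none invented),
  and `incorrect_stem`/`incorrect_suffix` (an invented boundary; *stem* if
  the first offending boundary lies at or before the end of the first
  linguistic segment, else *suffix*).  The stem/suffix split rule is this
  package's formalization of the category names.
* 2-vs-2 ties score 0.5 so accuracy stays an unbiased mean under degenerate
  predictors; cosine distance is clipped to [0, 2] against ulp-level
  rounding and errors on zero vectors rather than guessing.
* Permutation bijections include the identity (uniform over all
  permutations, not derangements).
* Ridge degenerate inputs: fewer than 4 training rows is an error;
  constant feature or target columns standardize with unit scale.

## Known limitations

* The skip-gram trainer is single-threaded Python/NumPy and is not meant
  for corpora beyond ~10⁶ tokens.
* The fast permutation mode holds regularization fixed at observed-run
  values; for very small word sets this couples the null weakly to the
  observed tuning.  The faithful mode exists but costs a full re-tune per
  permutation.
* Subsampling pairs (≤500 of 780 at the reference scale) adds Monte-Carlo
  noise to accuracies of order 0.01; the subsampling is seeded and recorded
  in every result.
* The per-word category counts for the published 170-stimulus
  morphological-segmentation comparison can be recomputed with
  `compare_segmentations`, but the per-word tables themselves are not
  redistributed with the package; place them under `data/supplementary/`
  to run that check.
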