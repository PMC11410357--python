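"""Word-label and segment-label permutation nulls for 2-vs-2 decoding.

Two null distributions are built by re-running the full leave-two-out
evaluation under randomized labelings:

* **word-label**: the assignment between brain-response rows and word-vector
  rows is shuffled by a uniform random permutation — the conventional chance
  level for decoding accuracy.
* **segment-label**: the *bijection between segment labels and segment
  vectors* is shuffled, word vectors are recomposed by summation, and the
  evaluation is re-run.  Because two words sharing a segment before the
  shuffle still share one vector term after it, this null retains the
  structure that summation alone induces in the word-vector set.  A decoding
  accuracy that clears the word-label threshold but not the segment-label
  threshold is therefore attributable to shared-segment structure rather
  than to information carried by the individual segment vectors.

Thresholds are the 95th percentile of the null by default; the empirical
p-value is ``(1 + #{null >= observed}) / (1 + n_perm)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .decoding import EpochsArray, WindowSpec, window_slices
from .embedding import SegmentVectorStore, WordVectorMatrix
from .evaluation import DecoderConfig, DecodingResult, PairwiseDecoder, make_pairs
from .segmentation import SegmentedLexicon

logger = logging.getLogger(__name__)

QUANTILE_METHODS = {"linear": "linear", "nearest-rank": "inverted_cdf"}


@dataclass
class PermutationResult:
    """Null distribution of 2-vs-2 accuracy with threshold and p-value."""

    kind: str  # "word_label" | "segment_label"
    null: np.ndarray  # (n_perm,)
    observed: float
    threshold: float
    p_value: float
    level: float
    seed: int
    window_center: float
    quantile_method: str = "linear"

    @property
    def n_perm(self) -> int:
        return len(self.null)

    @property
    def significant(self) -> bool:
        return self.observed > self.threshold


def empirical_threshold(
    null: np.ndarray, level: float = 0.95, method: str = "linear"
) -> float:
    """Quantile of the null distribution; ``linear`` interpolation between
    order statistics by default, ``nearest-rank`` on request."""
    if len(null) == 0:
        raise ValueError("empty null distribution")
    return float(np.quantile(np.asarray(null), level, method=QUANTILE_METHODS[method]))


def permutation_p_value(observed: float, null: np.ndarray) -> float:
    null = np.asarray(null)
    return float((1 + np.sum(null >= observed)) / (1 + len(null)))


def threshold_and_decide(
    observed: float,
    null: np.ndarray,
    level: float = 0.95,
    method: str = "linear",
) -> Dict[str, float | bool]:
    """Assess an observed accuracy against a permutation null: the verdict is
    ``observed > threshold``; the margin and empirical p-value are reported
    alongside."""
    thr = empirical_threshold(null, level, method)
    return {
        "threshold": thr,
        "significant": bool(observed > thr),
        "margin": float(observed - thr),
        "p_value": permutation_p_value(observed, null),
    }


def _align(
    epochs: EpochsArray, wordvecs: WordVectorMatrix
) -> Tuple[EpochsArray, np.ndarray]:
    """Align vectors to epochs by label, dropping words with no covered
    segments (logged)."""
    missing = [w for w in epochs.words if w not in wordvecs.words]
    if missing:
        raise KeyError(f"epochs words missing from word-vector matrix: {missing}")
    uncovered = set(wordvecs.uncovered_words)
    keep = [w for w in epochs.words if w not in uncovered]
    if len(keep) < len(epochs.words):
        logger.warning("dropping %d uncovered words", len(epochs.words) - len(keep))
        epochs = epochs.select_words(keep)
    return epochs, wordvecs.select(epochs.words).matrix


def _engine_at(
    epochs: EpochsArray,
    spec: WindowSpec,
    at_time: float,
    pairs: Sequence[Tuple[int, int]],
    config: DecoderConfig,
) -> Tuple[float, PairwiseDecoder]:
    """Build the pairwise engine for the window whose center is closest to
    ``at_time`` (seconds)."""
    slices = window_slices(epochs, spec)
    centers = np.array([c for c, _ in slices])
    w = int(np.argmin(np.abs(centers - at_time)))
    center, X = slices[w]
    engine = PairwiseDecoder(X, pairs, config)
    if config.alpha_scope == "per-window":
        engine.prepare_full(X)
    return center, engine


def word_label_null(
    epochs: EpochsArray,
    wordvecs: WordVectorMatrix,
    spec: Optional[WindowSpec] = None,
    n_perm: int = 1000,
    seed: int = 0,
    at_time: float = 0.4,
    config: Optional[DecoderConfig] = None,
    max_pairs: Optional[int] = None,
    level: float = 0.95,
    quantile_method: str = "linear",
    alpha_mode: str = "fast",
) -> PermutationResult:
    """Word-label permutation null at the window centered nearest ``at_time``.

    Each permutation shuffles the row assignment between brain responses and
    word vectors and re-runs the 2-vs-2 evaluation.  ``alpha_mode="fast"``
    (default) fixes the per-fold regularization strengths to the observed
    run's values inside the permutations; ``"faithful"`` re-tunes them in
    every permutation.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    spec = spec or WindowSpec()
    config = config or DecoderConfig()
    epochs, Y = _align(epochs, wordvecs)
    rng = np.random.default_rng(seed)
    pairs, _ = make_pairs(epochs.n_words, max_pairs, seed)
    center, engine = _engine_at(epochs, spec, at_time, pairs, config)
    outcomes, fold_alphas = engine.evaluate(Y)
    observed = float(outcomes.mean())
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(epochs.n_words)
        if alpha_mode == "fast":
            out_b, _ = engine.evaluate(Y[perm], alphas=fold_alphas)
        else:
            out_b, _ = engine.evaluate(Y[perm])
        null[b] = out_b.mean()
    return PermutationResult(
        kind="word_label",
        null=null,
        observed=observed,
        threshold=empirical_threshold(null, level, quantile_method),
        p_value=permutation_p_value(observed, null),
        level=level,
        seed=seed,
        window_center=center,
        quantile_method=quantile_method,
    )


@dataclass
class TimecourseNull:
    """Observed accuracy time course with a per-window word-label null.

    One label permutation is drawn per null sample and applied across all
    windows, so the null time courses inherit the temporal structure of a
    single mislabelling.
    """

    window_centers: np.ndarray
    observed: np.ndarray  # (n_windows,)
    null: np.ndarray  # (n_perm, n_windows)
    thresholds: np.ndarray  # (n_windows,)
    level: float
    seed: int


def word_label_null_timecourse(
    epochs: EpochsArray,
    wordvecs: WordVectorMatrix,
    spec: Optional[WindowSpec] = None,
    n_perm: int = 200,
    seed: int = 0,
    config: Optional[DecoderConfig] = None,
    max_pairs: Optional[int] = None,
    level: float = 0.95,
) -> TimecourseNull:
    """Observed accuracy and word-label null for every window.

    The observed run tunes the regularization per fold; the permutations
    reuse the observed per-fold strengths (fast mode).
    """
    spec = spec or WindowSpec()
    config = config or DecoderConfig()
    epochs, Y = _align(epochs, wordvecs)
    rng = np.random.default_rng(seed)
    pairs, _ = make_pairs(epochs.n_words, max_pairs, seed)
    perms = [rng.permutation(epochs.n_words) for _ in range(n_perm)]
    centers, observed, null_cols = [], [], []
    for center, X in window_slices(epochs, spec):
        engine = PairwiseDecoder(X, pairs, config)
        if config.alpha_scope == "per-window":
            engine.prepare_full(X)
        out, fold_alphas = engine.evaluate(Y)
        col = np.empty(n_perm)
        for b, perm in enumerate(perms):
            out_b, _ = engine.evaluate(Y[perm], alphas=fold_alphas)
            col[b] = out_b.mean()
        centers.append(center)
        observed.append(out.mean())
        null_cols.append(col)
    null = np.column_stack(null_cols)
    thresholds = np.array([empirical_threshold(null[:, w], level) for w in range(null.shape[1])])
    return TimecourseNull(
        window_centers=np.array(centers),
        observed=np.array(observed),
        null=null,
        thresholds=thresholds,
        level=level,
        seed=seed,
    )


def permute_segment_store(
    store: SegmentVectorStore,
    rng: np.random.Generator | int,
    restrict_to: Optional[Sequence[str]] = None,
) -> SegmentVectorStore:
    """Shuffle the bijection between segment labels and segment vectors.

    The permutation is uniform over all bijections (the identity is
    possible) of the labels in ``restrict_to`` — normally the segment types
    of the stimulus words under study; labels outside the set keep their
    vectors.  The multiset of vectors is preserved exactly.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    labels = [l for l in (restrict_to if restrict_to is not None else store.labels)]
    labels = [l for l in labels if l in store]
    if len(labels) < 2:
        raise ValueError("need at least 2 segments to permute")
    perm = rng.permutation(len(labels))
    vectors = dict(store.vectors)
    originals = [store[l] for l in labels]
    for l, k in zip(labels, perm):
        vectors[l] = originals[k]
    return SegmentVectorStore(vectors=vectors, dim=store.dim)


def _occurrence_matrix(
    lexicon: SegmentedLexicon, words: Sequence[str], labels: Sequence[str]
) -> np.ndarray:
    """(n_words x n_labels) segment-occurrence counts; composition by
    summation is then the product of this matrix with the stacked segment
    vectors, which permutations leave column-permuted only."""
    col = {l: k for k, l in enumerate(labels)}
    C = np.zeros((len(words), len(labels)))
    for i, w in enumerate(words):
        for seg in lexicon.segments_of(w):
            if seg in col:
                C[i, col[seg]] += 1.0
    return C


def segment_label_null(
    epochs: EpochsArray,
    lexicon: SegmentedLexicon,
    store: SegmentVectorStore,
    spec: Optional[WindowSpec] = None,
    n_perm: int = 1000,
    seed: int = 0,
    at_time: float = 0.4,
    config: Optional[DecoderConfig] = None,
    max_pairs: Optional[int] = None,
    level: float = 0.95,
    quantile_method: str = "linear",
    alpha_mode: str = "fast",
) -> PermutationResult:
    """Segment-label permutation null at the window centered nearest
    ``at_time``.

    Each permutation draws a fresh uniform bijection over the segment types
    of the words under study, recomposes every word vector by summation, and
    re-runs the 2-vs-2 evaluation.  The identity bijection reproduces the
    observed accuracy.  Words with no covered segment are dropped (as in the
    observed run).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    spec = spec or WindowSpec()
    config = config or DecoderConfig()
    labels = [l for l in lexicon.segment_types(epochs.words) if l in store]
    if len(labels) < 2:
        raise ValueError("need at least 2 covered segments to permute")
    C = _occurrence_matrix(lexicon, epochs.words, labels)
    covered = C.sum(axis=1) > 0
    if not np.all(covered):
        dropped = [w for w, c in zip(epochs.words, covered) if not c]
        logger.warning("dropping %d uncovered words: %s", len(dropped), dropped)
        epochs = epochs.select_words([w for w, c in zip(epochs.words, covered) if c])
        C = C[covered]
    S = np.stack([store[l] for l in labels])  # (n_labels, D)
    Y = C @ S
    rng = np.random.default_rng(seed)
    pairs, _ = make_pairs(epochs.n_words, max_pairs, seed)
    center, engine = _engine_at(epochs, spec, at_time, pairs, config)
    outcomes, fold_alphas = engine.evaluate(Y)
    observed = float(outcomes.mean())
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(len(labels))
        Yb = C @ S[perm]
        if alpha_mode == "fast":
            out_b, _ = engine.evaluate(Yb, alphas=fold_alphas)
        else:
            out_b, _ = engine.evaluate(Yb)
        null[b] = out_b.mean()
    return PermutationResult(
        kind="segment_label",
        null=null,
        observed=observed,
        threshold=empirical_threshold(null, level, quantile_method),
        p_value=permutation_p_value(observed, null),
        level=level,
        seed=seed,
        window_center=center,
        quantile_method=quantile_method,
    )
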