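"""Desk-scale study runs: the synthetic dissociation experiment and the
type-I calibration of the word-label test.

These functions define the package's reference study conditions.  The
dissociation study mirrors the full analysis on a synthetic dataset small
enough for a single CPU: 40 multimorphemic words (20 stems x 2 suffixes),
20-dimensional word vectors, 6 sensors sampled at 100 Hz (60 features per
100-ms window), a 350-500 ms effect window at SNR 5, 100 permutations per
null, and up to 500 subsampled word pairs.  Three decoding runs are
compared at the 400-ms window:

* **morphological** — the true segmentation with the true segment vectors;
  accuracy should clear both the word-label and the segment-label threshold;
* **random segmentation** — random splits paired with a meaningless
  (shuffled) vector store; accuracy may clear the word-label threshold but
  not the segment-label threshold;
* **1-gram** — character segmentation, where heavy segment sharing drives
  the segment-label threshold well above the word-label threshold.

The type-I calibration simulates the null (SNR 0) repeatedly and measures
how often the word-label test rejects at its 95th-percentile threshold.
"""

from __future__ import annotations

from dataclasses import asdict, replace
from typing import Dict, Optional

import numpy as np

from .decoding import apply_baseline, n_windows
from .embedding import SegmentVectorStore, compose_word_vectors
from .evaluation import DecoderConfig
from .permutation import (
    empirical_threshold,
    permutation_p_value,
    segment_label_null,
    word_label_null,
    word_label_null_timecourse,
)
from .segmentation import SegmentationScheme, build_lexicon
from .synthetic import SyntheticConfig, make_dataset

#: Study conditions of the synthetic dissociation experiment.
DISSOCIATION_CONFIG = SyntheticConfig(
    n_stems=20,
    n_suffixes=2,
    suffixes_per_word=1,
    dim=20,
    n_sensors=6,
    sfreq=100.0,
    tmin=-0.2,
    tmax=0.8,
    effect_window=(0.35, 0.50),
    snr=5.0,
    semantic_clusters=4,
)

#: Reduced conditions for the type-I calibration (null data, many replicates).
CALIBRATION_CONFIG = SyntheticConfig(
    n_stems=8,
    n_suffixes=2,
    suffixes_per_word=1,
    dim=8,
    n_sensors=10,
    sfreq=100.0,
    snr=0.0,
    semantic_clusters=4,
)

EFFECT_TIME = 0.4  # comparison window center, seconds


def _random_store_for(labels, dim: int, rng: np.random.Generator) -> SegmentVectorStore:
    """A vector store with no semantic link to its labels: i.i.d. standard
    normal vectors, assignment shuffled."""
    vecs = rng.standard_normal((len(labels), dim))
    order = rng.permutation(len(labels))
    return SegmentVectorStore({l: vecs[k] for l, k in zip(labels, order)}, dim)


def dissociation_study(
    seed: int = 0,
    n_perm: int = 100,
    max_pairs: int = 500,
    config: Optional[SyntheticConfig] = None,
) -> Dict:
    """Run the three-way dissociation experiment.

    Returns a dict with, per run, the observed accuracy at the 400-ms
    window and the word-label / segment-label thresholds, plus the
    morphological run's full accuracy time course with its per-window
    word-label null band.
    """
    config = replace(config or DISSOCIATION_CONFIG, seed=seed)
    epochs, truth = make_dataset(config)
    ep = apply_baseline(epochs)
    dec = DecoderConfig()

    # -- morphological run: true lexicon, true segment vectors -------------
    tc = word_label_null_timecourse(
        ep, truth.wordvecs, n_perm=n_perm, seed=seed, config=dec, max_pairs=max_pairs
    )
    w_eff = int(np.argmin(np.abs(tc.window_centers - EFFECT_TIME)))
    morph_seg = segment_label_null(
        ep, truth.lexicon, truth.store, n_perm=n_perm, seed=seed,
        at_time=EFFECT_TIME, config=dec, max_pairs=max_pairs,
    )

    # -- random segmentation with a meaningless vector store ---------------
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    rand_lex = build_lexicon(truth.words, SegmentationScheme(name="random", seed=seed + 101))
    rand_store = _random_store_for(rand_lex.segment_types(), config.dim, rng)
    rand_seg = segment_label_null(
        ep, rand_lex, rand_store, n_perm=n_perm, seed=seed,
        at_time=EFFECT_TIME, config=dec, max_pairs=max_pairs,
    )
    rand_wv = compose_word_vectors(rand_lex, rand_store, truth.words)
    rand_word = word_label_null(
        ep, rand_wv, n_perm=n_perm, seed=seed, at_time=EFFECT_TIME,
        config=dec, max_pairs=max_pairs,
    )

    # -- 1-gram segmentation ------------------------------------------------
    uni_lex = build_lexicon(truth.words, SegmentationScheme(name="ngram", k=1))
    uni_store = _random_store_for(uni_lex.segment_types(), config.dim, rng)
    uni_seg = segment_label_null(
        ep, uni_lex, uni_store, n_perm=n_perm, seed=seed,
        at_time=EFFECT_TIME, config=dec, max_pairs=max_pairs,
    )
    uni_wv = compose_word_vectors(uni_lex, uni_store, truth.words)
    uni_word = word_label_null(
        ep, uni_wv, n_perm=n_perm, seed=seed, at_time=EFFECT_TIME,
        config=dec, max_pairs=max_pairs,
    )

    null_lo = np.quantile(tc.null, 0.025, axis=0)
    null_hi = np.quantile(tc.null, 0.975, axis=0)
    return {
        "config": asdict(config),
        "n_perm": n_perm,
        "max_pairs": max_pairs,
        "window_centers": tc.window_centers,
        "morph": {
            "timecourse": tc.observed,
            "word_label_thresholds": tc.thresholds,
            "null_band_lo": null_lo,
            "null_band_hi": null_hi,
            "observed": float(tc.observed[w_eff]),
            "word_label_threshold": float(tc.thresholds[w_eff]),
            "segment_label_threshold": morph_seg.threshold,
            "segment_label_p": morph_seg.p_value,
            "word_label_null": tc.null[:, w_eff],
        },
        "random": {
            "observed": rand_seg.observed,
            "word_label_threshold": rand_word.threshold,
            "segment_label_threshold": rand_seg.threshold,
            "segment_label_p": rand_seg.p_value,
        },
        "unigram": {
            "observed": uni_seg.observed,
            "word_label_threshold": uni_word.threshold,
            "segment_label_threshold": uni_seg.threshold,
        },
    }


def type1_calibration(
    seed: int = 0,
    n_replicates: int = 200,
    n_perm: int = 100,
    config: Optional[SyntheticConfig] = None,
) -> Dict:
    """Estimate the word-label test's type-I error rate under the null.

    Each replicate simulates a fresh SNR-0 dataset, computes the observed
    accuracy at the 400-ms window, builds the word-label null, and records
    whether the observed accuracy exceeds the 95th-percentile threshold.
    The rejection rate should be close to the nominal 5%.
    """
    base = config or CALIBRATION_CONFIG
    rejections = np.zeros(n_replicates, bool)
    observed = np.empty(n_replicates)
    for r in range(n_replicates):
        cfg = replace(base, seed=(seed * 100_003 + r) % (2**31 - 1))
        epochs, truth = make_dataset(cfg)
        ep = apply_baseline(epochs)
        res = word_label_null(
            ep, truth.wordvecs, n_perm=n_perm, seed=cfg.seed + 1, at_time=EFFECT_TIME
        )
        observed[r] = res.observed
        rejections[r] = res.observed > res.threshold
    rate = float(rejections.mean())
    return {
        "n_replicates": n_replicates,
        "n_perm": n_perm,
        "rejection_rate": rate,
        "rejection_se": float(np.sqrt(rate * (1 - rate) / n_replicates)) if 0 < rate < 1 else float(np.sqrt(0.05 * 0.95 / n_replicates)),
        "mean_observed": float(observed.mean()),
        "config": asdict(base),
    }


def chance_behavior(seed: int = 0, n_perm: int = 100, config: Optional[SyntheticConfig] = None) -> Dict:
    """Observed accuracy on one SNR-0 dataset against its own word-label
    null: the deviation from 0.5 in units of the null's empirical SD."""
    cfg = replace(config or CALIBRATION_CONFIG, seed=seed)
    epochs, truth = make_dataset(cfg)
    ep = apply_baseline(epochs)
    res = word_label_null(ep, truth.wordvecs, n_perm=n_perm, seed=seed + 1, at_time=EFFECT_TIME)
    se = float(res.null.std(ddof=1))
    return {
        "observed": res.observed,
        "null_mean": float(res.null.mean()),
        "null_sd": se,
        "deviation_in_se": float(abs(res.observed - 0.5) / se),
        "config": asdict(cfg),
    }
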