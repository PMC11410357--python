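"""Synthetic study generator: multimorphemic lexicon, structured segment
vectors, toy corpus, and simulated evoked responses.

The generator reproduces the statistical structure the decoding analysis
relies on, at desk scale:

* an artificial **multimorphemic lexicon** — words are ``stem + 1..2
  suffixes`` from a closed suffix set, so every suffix is shared by many
  words while every stem is rare.  This shared-suffix structure is exactly
  what makes the segment-label permutation test informative;
* **segment vectors** in which stems carry cluster semantics (isotropic
  noise around one of a few cluster centroids) and suffixes live in a
  disjoint lower-norm subspace, emulating the semantic/grammatical split a
  distributional model learns;
* an optional **toy corpus** that places same-cluster words in shared
  contexts so a skip-gram model can actually be trained end to end, with an
  out-of-vocabulary mode in which no sentence contains any stimulus surface
  form;
* simulated **evoked responses** that are a noisy linear sensor projection
  of the composed word vectors, gated by a raised-cosine temporal envelope
  confined to an effect window (350-500 ms by default), with a signal-free
  baseline.  SNR is the ratio of signal RMS to noise RMS over the effect
  window, averaged across sensors; SNR 0 gives pure noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .decoding import EpochsArray
from .embedding import SegmentVectorStore, WordVectorMatrix, compose_word_vectors
from .segmentation import SegmentationScheme, SegmentedLexicon

ALPHABET = "abcdefghijklmnoprstuvyäö"  # Finnish-ish; no q/w/x/z


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study.

    Defaults mirror the real recording geometry (204 planar gradiometers,
    1000 Hz, epochs -200..800 ms) and an effect window of 350-500 ms.
    """

    n_stems: int = 20
    n_suffixes: int = 4
    suffixes_per_word: int = 1
    dim: int = 20
    n_sensors: int = 204
    sfreq: float = 1000.0
    tmin: float = -0.2
    tmax: float = 0.8
    effect_window: Tuple[float, float] = (0.35, 0.50)
    snr: float = 1.0
    semantic_clusters: int = 4
    seed: int = 0
    stem_len: Tuple[int, int] = (4, 8)
    suffix_len: Tuple[int, int] = (1, 3)
    cluster_scale: float = 3.0
    stem_noise_scale: float = 1.0
    suffix_scale: float = 2.5
    ar1_coef: float = 0.0  # optional AR(1) temporal noise correlation

    def __post_init__(self) -> None:
        if self.snr < 0:
            raise ValueError("snr must be >= 0")
        if self.suffixes_per_word not in (1, 2):
            raise ValueError("suffixes_per_word must be 1 or 2")
        t0, t1 = self.effect_window
        if not (self.tmin <= t0 < t1 <= self.tmax):
            raise ValueError("effect window must lie within the epoch")
        if self.dim < self.semantic_clusters:
            raise ValueError("dim must be >= semantic_clusters")
        if self.n_stems * self.n_suffixes < 4:
            raise ValueError("need at least 4 words (n_stems * n_suffixes >= 4)")


@dataclass
class GroundTruth:
    """Everything needed to reconstruct the simulated signal exactly."""

    lexicon: SegmentedLexicon
    words: List[str]
    store: SegmentVectorStore
    wordvecs: WordVectorMatrix
    mixing: np.ndarray  # (n_sensors, dim)
    envelope: np.ndarray  # per-sample gain
    stem_cluster: Dict[str, int]
    config: SyntheticConfig


def _random_string(rng: np.random.Generator, lo: int, hi: int) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "".join(rng.choice(list(ALPHABET), size=n))


def generate_lexicon(config: SyntheticConfig) -> Tuple[SegmentedLexicon, List[str], Dict[str, int]]:
    """Build the artificial multimorphemic lexicon.

    Every (stem, suffix) combination yields one word; with two suffix slots a
    second, distinct suffix is appended.  The true morphological
    segmentation is recorded.  Returns (lexicon, word list, stem->cluster
    assignment); stems are assigned to semantic clusters round-robin.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    for _attempt in range(50):
        stems: List[str] = []
        while len(stems) < config.n_stems:
            s = _random_string(rng, *config.stem_len)
            if s not in stems:
                stems.append(s)
        suffixes: List[str] = []
        while len(suffixes) < config.n_suffixes:
            s = _random_string(rng, *config.suffix_len)
            if s not in suffixes and s not in stems:
                suffixes.append(s)
        entries: Dict[str, List[str]] = {}
        ok = True
        for stem in stems:
            for suf in suffixes:
                segs = [stem, suf]
                if config.suffixes_per_word == 2:
                    others = [s for s in suffixes if s != suf]
                    segs.append(others[int(rng.integers(len(others)))])
                word = "".join(segs)
                if word in entries or word in stems or word in suffixes:
                    ok = False
                    break
                entries[word] = segs
            if not ok:
                break
        if ok:
            scheme = SegmentationScheme(name="lexicon", source_path="synthetic:ground-truth")
            lexicon = SegmentedLexicon(entries=entries, scheme=scheme)
            stem_cluster = {s: i % config.semantic_clusters for i, s in enumerate(stems)}
            return lexicon, list(entries), stem_cluster
    raise RuntimeError("could not build a collision-free lexicon; enlarge stem lengths")


def generate_segment_vectors(
    lexicon: SegmentedLexicon,
    config: SyntheticConfig,
    stem_cluster: Optional[Dict[str, int]] = None,
) -> SegmentVectorStore:
    """Structured segment vectors for the lexicon's segment types.

    Stems (first segments) are cluster centroids plus isotropic noise in the
    leading "semantic" coordinates; suffixes (non-first segments) occupy the
    complementary trailing coordinates with smaller norm, hence are exactly
    orthogonal to every stem centroid.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    stems, suffixes = [], []
    for segs in lexicon.entries.values():
        if segs[0] not in stems:
            stems.append(segs[0])
        for s in segs[1:]:
            if s not in suffixes:
                suffixes.append(s)
    if stem_cluster is None:
        stem_cluster = {s: i % config.semantic_clusters for i, s in enumerate(stems)}
    D = config.dim
    d_suf = max(1, D // 5)
    d_stem = D - d_suf
    centroids = rng.normal(scale=config.cluster_scale, size=(config.semantic_clusters, d_stem))
    vectors: Dict[str, np.ndarray] = {}
    for stem in stems:
        v = np.zeros(D)
        v[:d_stem] = centroids[stem_cluster[stem]] + rng.normal(
            scale=config.stem_noise_scale, size=d_stem
        )
        vectors[stem] = v
    for suf in suffixes:
        v = np.zeros(D)
        v[d_stem:] = rng.normal(scale=config.suffix_scale, size=d_suf)
        vectors[suf] = v
    return SegmentVectorStore(vectors=vectors, dim=D)


def generate_corpus(
    lexicon: SegmentedLexicon,
    config: SyntheticConfig,
    min_frequency: int = 50,
    words_per_sentence: int = 4,
    exclude_targets: bool = False,
    stem_cluster: Optional[Dict[str, int]] = None,
) -> List[List[str]]:
    """Toy sentence corpus over the stimulus vocabulary.

    Each sentence draws one semantic cluster, interleaves words whose stems
    belong to that cluster with cluster-specific filler tokens, and the
    corpus is grown until every stimulus word (hence every segment) appears
    at least ``min_frequency`` times.  With ``exclude_targets=True`` no
    sentence contains any stimulus surface form: segments appear as
    free-standing tokens instead (the out-of-vocabulary regime).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    words = list(lexicon.entries)
    if stem_cluster is None:
        stems = list(dict.fromkeys(segs[0] for segs in lexicon.entries.values()))
        stem_cluster = {s: i % config.semantic_clusters for i, s in enumerate(stems)}
    by_cluster: Dict[int, List[str]] = {c: [] for c in range(config.semantic_clusters)}
    for w in words:
        by_cluster[stem_cluster[lexicon.segments_of(w)[0]]].append(w)
    fillers = {
        c: [f"filler{c}x{i}" for i in range(3)] for c in range(config.semantic_clusters)
    }
    counts = {w: 0 for w in words}
    sentences: List[List[str]] = []
    while min(counts.values()) < min_frequency:
        c = int(rng.integers(config.semantic_clusters))
        pool = by_cluster[c]
        chosen = [pool[int(rng.integers(len(pool)))] for _ in range(words_per_sentence)]
        sent: List[str] = []
        for w in chosen:
            sent.append(fillers[c][int(rng.integers(3))])
            if exclude_targets:
                sent.extend(lexicon.segments_of(w))
            else:
                sent.append(w)
            counts[w] += 1
        sentences.append(sent)
    if exclude_targets:
        target_set = set(words)
        assert not any(t in target_set for s in sentences for t in s)
    return sentences


def raised_cosine_envelope(times: np.ndarray, window: Tuple[float, float]) -> np.ndarray:
    """Smooth bump supported exactly on ``window``: 0.5 * (1 - cos(2*pi*u))
    with u the normalized position inside the window; zero elsewhere."""
    t0, t1 = window
    u = (times - t0) / (t1 - t0)
    env = 0.5 * (1.0 - np.cos(2.0 * np.pi * u))
    env[(u < 0) | (u > 1)] = 0.0
    return env


def simulate_epochs(truth: GroundTruth, config: Optional[SyntheticConfig] = None) -> EpochsArray:
    """Simulate item-averaged evoked responses.

    ``data[w, s, t] = envelope(t) * (mixing @ v_w)[s] * gain + noise`` with
    standard Gaussian white noise (optionally AR(1)-correlated over time).
    The gain is chosen so that the ratio of signal RMS to noise RMS over the
    effect window equals ``config.snr``; at snr=0 the data are pure noise.
    """
    config = config or truth.config
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    n_times = int(round((config.tmax - config.tmin) * config.sfreq))
    times = config.tmin + np.arange(n_times) / config.sfreq
    env = truth.envelope
    if env.shape[0] != n_times:
        raise ValueError("envelope length does not match the epoch")
    proj = truth.wordvecs.matrix @ truth.mixing.T  # (n_words, n_sensors)
    signal = proj[:, :, None] * env[None, None, :]
    noise = rng.standard_normal(signal.shape)
    if config.ar1_coef:
        rho = config.ar1_coef
        for t in range(1, n_times):
            noise[:, :, t] = rho * noise[:, :, t - 1] + np.sqrt(1 - rho**2) * noise[:, :, t]
    in_window = env > 0
    sig_rms = np.sqrt(np.mean(signal[:, :, in_window] ** 2))
    gain = 0.0 if sig_rms == 0 else config.snr / sig_rms  # noise RMS is 1
    data = signal * gain + noise
    return EpochsArray(data, config.sfreq, config.tmin, list(truth.words))


def make_dataset(config: SyntheticConfig) -> Tuple[EpochsArray, GroundTruth]:
    """Generate a complete synthetic study: lexicon, segment vectors,
    composed word vectors, mixing matrix, envelope, and simulated epochs.
    Deterministic given ``config`` (all randomness derives from
    ``config.seed``)."""
    lexicon, words, stem_cluster = generate_lexicon(config)
    store = generate_segment_vectors(lexicon, config, stem_cluster)
    wordvecs = compose_word_vectors(lexicon, store, words)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 5]))
    mixing = rng.standard_normal((config.n_sensors, config.dim)) / np.sqrt(config.dim)
    n_times = int(round((config.tmax - config.tmin) * config.sfreq))
    times = config.tmin + np.arange(n_times) / config.sfreq
    envelope = raised_cosine_envelope(times, config.effect_window)
    truth = GroundTruth(
        lexicon=lexicon,
        words=words,
        store=store,
        wordvecs=wordvecs,
        mixing=mixing,
        envelope=envelope,
        stem_cluster=stem_cluster,
        config=config,
    )
    return simulate_epochs(truth, config), truth
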