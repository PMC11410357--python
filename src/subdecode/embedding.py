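"""Segment vectors: skip-gram training, summation composition, vector-space
utilities.

The distributional model is a skip-gram network with negative sampling: a
segment's vector is the hidden-layer weight row learned while predicting the
segments surrounding it within a symmetric context window.  Stimulus-word
vectors are then composed as the *sum* of the vectors of the word's segments,
so a word absent from the corpus can still be represented as long as its
segments were frequent enough to be trained.

The trainer here is a compact NumPy implementation intended for corpora of up
to a few hundred thousand tokens; it follows the standard formulation
(unigram^0.75 negative-sampling distribution, linearly decaying learning
rate) and is validated against the qualitative distributional property that
segments sharing contexts end up close under cosine distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist

from .segmentation import SegmentationScheme, SegmentedLexicon, segment_corpus_stream

logger = logging.getLogger(__name__)


@dataclass
class EmbeddingConfig:
    """Hyperparameters of the segment-vector model.

    ``dim`` (default 300) and ``context_window`` (default 7) are the model's
    two structural hyperparameters; ``min_count`` (default 50) drops segments
    too rare for a reliable vector.  ``exclude_sentences_containing`` removes
    every sentence containing any listed surface word before segmentation —
    the out-of-vocabulary regime in which target-word vectors can only be
    composed from segments learned elsewhere.
    """

    dim: int = 300
    context_window: int = 7
    min_count: int = 50
    training_mode: str = "skipgram"
    exclude_sentences_containing: Optional[Set[str]] = None
    negative: int = 5
    epochs: int = 5
    learning_rate: float = 0.025
    min_learning_rate: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dim < 1 or self.context_window < 1 or self.min_count < 1:
            raise ValueError("dim, context_window and min_count must all be >= 1")
        if self.training_mode != "skipgram":
            raise ValueError(f"unsupported training mode {self.training_mode!r}")


@dataclass
class SegmentVectorStore:
    """Mapping segment label -> real vector of fixed dimension."""

    vectors: Dict[str, np.ndarray]
    dim: int

    def __post_init__(self) -> None:
        for label, vec in self.vectors.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (self.dim,):
                raise ValueError(f"vector for {label!r} has shape {vec.shape}, expected ({self.dim},)")
            if not np.all(np.isfinite(vec)):
                raise ValueError(f"vector for {label!r} contains non-finite entries")
            self.vectors[label] = vec

    def __contains__(self, label: str) -> bool:
        return label in self.vectors

    def __getitem__(self, label: str) -> np.ndarray:
        return self.vectors[label]

    def __len__(self) -> int:
        return len(self.vectors)

    @property
    def labels(self) -> List[str]:
        return list(self.vectors)


@dataclass
class WordVectorMatrix:
    """Composed word vectors: row ``i`` of ``matrix`` is the vector of
    ``words[i]``; ``coverage`` records which segments were found / missing."""

    words: List[str]
    matrix: np.ndarray
    coverage: Dict[str, Dict[str, List[str]]]

    @property
    def uncovered_words(self) -> List[str]:
        """Words none of whose segments had a vector; their rows are zero and
        they must be excluded from decoder training by the caller."""
        return [w for w in self.words if not self.coverage[w]["found"]]

    def select(self, words: Sequence[str]) -> "WordVectorMatrix":
        idx = {w: i for i, w in enumerate(self.words)}
        rows = [idx[w] for w in words]
        return WordVectorMatrix(
            words=list(words),
            matrix=self.matrix[rows],
            coverage={w: self.coverage[w] for w in words},
        )


def _iter_segmented_sentences(
    sentences: Iterable[Sequence[str]],
    config: EmbeddingConfig,
    scheme: Optional[SegmentationScheme],
    lexicon: Optional[SegmentedLexicon],
) -> List[List[str]]:
    excl = config.exclude_sentences_containing
    cache: Dict[str, List[str]] = {}
    rng = np.random.default_rng(scheme.seed) if scheme is not None and scheme.name == "random" else None
    out: List[List[str]] = []
    for sent in sentences:
        toks = list(sent)
        if excl and any(t in excl for t in toks):
            continue
        if scheme is None:
            out.append(toks)
        else:
            out.append(list(segment_corpus_stream(toks, scheme, lexicon=lexicon, rng=rng, _cache=cache)))
    return out


def train_segment_vectors(
    sentences: Iterable[Sequence[str]],
    config: EmbeddingConfig,
    scheme: Optional[SegmentationScheme] = None,
    lexicon: Optional[SegmentedLexicon] = None,
) -> SegmentVectorStore:
    """Train skip-gram segment vectors on a (surface-form) sentence corpus.

    Sentences are lists of surface tokens.  If ``scheme`` is given, each
    sentence is segmented in place before training; otherwise the tokens are
    taken to be segments already.  Only segments with corpus frequency
    ``>= config.min_count`` receive a vector.
    """
    corpus = _iter_segmented_sentences(sentences, config, scheme, lexicon)
    if not corpus or not any(corpus):
        raise ValueError("corpus is empty after sentence exclusion")

    freq: Dict[str, int] = {}
    for sent in corpus:
        for tok in sent:
            freq[tok] = freq.get(tok, 0) + 1
    vocab = [t for t, c in freq.items() if c >= config.min_count]
    if not vocab:
        raise ValueError(
            f"no segment reaches min_count={config.min_count}; most frequent count is "
            f"{max(freq.values())}"
        )
    index = {t: i for i, t in enumerate(vocab)}
    counts = np.array([freq[t] for t in vocab], dtype=float)

    rng = np.random.default_rng(config.seed)
    V, D = len(vocab), config.dim
    # standard word2vec initialisation: input uniform, output zeros
    w_in = (rng.random((V, D)) - 0.5) / D
    w_out = np.zeros((V, D))

    noise = counts**0.75
    noise /= noise.sum()
    # precompute a large pool of negative samples for speed
    neg_pool = rng.choice(V, size=max(100_000, 20 * int(counts.sum())), p=noise)
    neg_ptr = 0

    ids_corpus = [[index[t] for t in sent if t in index] for sent in corpus]
    ids_corpus = [s for s in ids_corpus if len(s) >= 2]
    total_centers = sum(len(s) for s in ids_corpus) * config.epochs
    seen = 0
    lr0, lr_min = config.learning_rate, config.min_learning_rate
    window = config.context_window
    k_neg = config.negative

    for _epoch in range(config.epochs):
        for sent in ids_corpus:
            n = len(sent)
            arr = np.asarray(sent)
            for pos in range(n):
                lr = max(lr_min, lr0 * (1.0 - seen / max(1, total_centers)))
                seen += 1
                lo, hi = max(0, pos - window), min(n, pos + window + 1)
                ctx = np.concatenate([arr[lo:pos], arr[pos + 1 : hi]])
                if ctx.size == 0:
                    continue
                center = sent[pos]
                n_neg = k_neg * ctx.size
                if neg_ptr + n_neg > neg_pool.size:
                    neg_pool = rng.choice(V, size=neg_pool.size, p=noise)
                    neg_ptr = 0
                negs = neg_pool[neg_ptr : neg_ptr + n_neg]
                neg_ptr += n_neg
                targets = np.concatenate([ctx, negs])
                labels = np.zeros(targets.size)
                labels[: ctx.size] = 1.0
                v = w_in[center]
                out = w_out[targets]
                scores = out @ v
                g = (labels - 1.0 / (1.0 + np.exp(-scores))) * lr
                grad_in = g @ out
                np.add.at(w_out, targets, np.outer(g, v))
                w_in[center] = v + grad_in

    vectors = {t: w_in[index[t]].copy() for t in vocab}
    logger.info("trained %d segment vectors (dim=%d) on %d sentences", V, D, len(corpus))
    return SegmentVectorStore(vectors=vectors, dim=D)


def compose_word_vectors(
    lexicon: SegmentedLexicon,
    store: SegmentVectorStore,
    words: Sequence[str],
) -> WordVectorMatrix:
    """Compose each word's vector as the sum of its segment vectors.

    Segments absent from the store are skipped (with multiplicity respected
    for the segments that are present) and recorded per word in ``coverage``;
    a word with *no* covered segment keeps a zero row and is listed in
    :attr:`WordVectorMatrix.uncovered_words` for caller-side exclusion.
    """
    matrix = np.zeros((len(words), store.dim))
    coverage: Dict[str, Dict[str, List[str]]] = {}
    for i, word in enumerate(words):
        if word not in lexicon:
            raise KeyError(f"word {word!r} absent from segmentation lexicon")
        found: List[str] = []
        missing: List[str] = []
        for seg in lexicon.segments_of(word):
            if seg in store:
                matrix[i] += store[seg]
                found.append(seg)
            else:
                missing.append(seg)
        coverage[word] = {"found": found, "missing": missing}
        if missing:
            logger.warning("word %r: segments %s missing from vector store", word, missing)
    return WordVectorMatrix(words=list(words), matrix=matrix, coverage=coverage)


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine distance ``1 - u.v / (|u||v|)``, in [0, 2].

    Undefined (raises) for zero vectors.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine distance is undefined for zero vectors")
    # rounding can push the result a few ulp outside [0, 2]
    return float(min(2.0, max(0.0, 1.0 - (u @ v) / (nu * nv))))


def cluster_words(matrix: WordVectorMatrix) -> np.ndarray:
    """Complete-linkage hierarchical clustering of word vectors under cosine
    distance.  Returns the SciPy linkage matrix; merge heights are the longest
    pairwise cosine distance between the merged clusters."""
    X = matrix.matrix
    if X.shape[0] < 2:
        raise ValueError("clustering needs at least 2 words")
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0):
        zero = [matrix.words[i] for i in np.flatnonzero(norms == 0)]
        raise ValueError(f"zero word vectors cannot be clustered: {zero}")
    return linkage(pdist(X, metric="cosine"), method="complete")


def _sanitize_label(label: str) -> str:
    for ch in "(),:;[]":
        label = label.replace(ch, "_")
    return label.replace(" ", "_")


def dendrogram_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Export a linkage matrix as a Newick string with branch lengths equal
    to the difference between parent and child merge heights."""
    tree = to_tree(Z)

    def recurse(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{_sanitize_label(labels[node.id])}:{length:.6g}"
        left = recurse(node.left, node.dist)
        right = recurse(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return recurse(tree, tree.dist) + ";"


def write_vectors(store: SegmentVectorStore, path: str | Path) -> None:
    """Write a store in word2vec text format: header ``count dim``, then one
    ``label v1 ... vD`` line per segment."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(store)} {store.dim}\n")
        for label, vec in store.vectors.items():
            fh.write(label + " " + " ".join(repr(float(x)) for x in vec) + "\n")


def read_vectors(path: str | Path) -> SegmentVectorStore:
    """Read a word2vec text format vector file."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}: malformed word2vec header {header}")
        count, dim = int(header[0]), int(header[1])
        vectors: Dict[str, np.ndarray] = {}
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split(" ")
            if len(parts) != dim + 1:
                raise ValueError(
                    f"{path}:{lineno}: expected {dim + 1} fields, got {len(parts)}"
                )
            vectors[parts[0]] = np.array([float(x) for x in parts[1:]])
    if len(vectors) != count:
        raise ValueError(f"{path}: header declares {count} vectors, file has {len(vectors)}")
    return SegmentVectorStore(vectors=vectors, dim=dim)
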