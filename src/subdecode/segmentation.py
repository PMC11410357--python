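"""Word segmentation schemes and segmentation-lexicon handling.

A *segmentation scheme* maps a written word form to an ordered list of
contiguous subword segments.  Four schemes are supported:

``whole``
    No segmentation; the word is its own single segment.
``ngram``
    Left-to-right chunks of ``k`` characters, final chunk possibly shorter.
``random``
    The word is split at ``n - 1`` interior positions drawn uniformly without
    replacement, where ``n`` itself is drawn from the discrete uniform over
    ``{2, ..., floor(l / 2)}`` for a word of length ``l``.  Words of length
    three or fewer are left whole (the draw set is empty).  Segmentation is
    cached per word type so every occurrence of a word receives the identical
    split.
``lexicon``
    Segmentations are supplied externally (e.g. a linguistic analyzer or a
    statistical morphology model such as Morfessor) as a TSV file.

All strings are treated as sequences of Unicode code points; word lengths are
code-point counts, which matters for Finnish ``ä``/``ö``.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np

logger = logging.getLogger(__name__)

SCHEME_NAMES = ("whole", "ngram", "random", "lexicon")

COMPARISON_CATEGORIES = (
    "identical",
    "unsegmented",
    "incomplete",
    "incorrect_stem",
    "incorrect_suffix",
)


@dataclass(frozen=True)
class SegmentationScheme:
    """Description of one segmentation scheme.

    Parameters
    ----------
    name
        One of ``whole``, ``ngram``, ``random``, ``lexicon``.
    k
        n-gram length; required iff ``name == "ngram"``.
    seed
        Random seed; required iff ``name == "random"`` so that a scheme
        instance always reproduces the same segmentation.
    source_path
        Path of the external lexicon; required iff ``name == "lexicon"``.
    """

    name: str
    k: Optional[int] = None
    seed: Optional[int] = None
    source_path: Optional[str] = None

    def __post_init__(self) -> None:
        if self.name not in SCHEME_NAMES:
            raise ValueError(f"unknown scheme name {self.name!r}; expected one of {SCHEME_NAMES}")
        if self.name == "ngram":
            if self.k is None or self.k < 1:
                raise ValueError("ngram scheme requires k >= 1")
        if self.name == "random" and self.seed is None:
            raise ValueError("random scheme requires a seed")
        if self.name == "lexicon" and self.source_path is None:
            raise ValueError("lexicon scheme requires source_path")


@dataclass
class SegmentedLexicon:
    """Ordered mapping of word -> list of segment labels under one scheme."""

    entries: Dict[str, List[str]]
    scheme: SegmentationScheme

    def __post_init__(self) -> None:
        for word, segs in self.entries.items():
            if not segs:
                raise ValueError(f"word {word!r} has no segments")

    @property
    def words(self) -> List[str]:
        return list(self.entries)

    def segments_of(self, word: str) -> List[str]:
        return list(self.entries[word])

    def segment_types(self, words: Optional[Sequence[str]] = None) -> List[str]:
        """Unique segment types occurring in the given words (default: all),
        in first-occurrence order."""
        seen: Dict[str, None] = {}
        for w in self.entries if words is None else words:
            for s in self.entries[w]:
                seen.setdefault(s, None)
        return list(seen)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, word: str) -> bool:
        return word in self.entries


def segment_whole(word: str) -> List[str]:
    """Return the word as a single segment (the whole-word scheme)."""
    if not word:
        raise ValueError("cannot segment the empty string")
    return [word]


def segment_ngram(word: str, k: int) -> List[str]:
    """Chunk ``word`` into contiguous, non-overlapping ``k``-character
    segments, left to right; the final segment may be shorter."""
    if not word:
        raise ValueError("cannot segment the empty string")
    if k < 1:
        raise ValueError(f"n-gram length must be >= 1, got {k}")
    return [word[i : i + k] for i in range(0, len(word), k)]


def segment_random(word: str, rng: np.random.Generator) -> List[str]:
    """Split ``word`` at random interior positions.

    The number of segments ``n`` is drawn from the discrete uniform over
    ``{2, ..., floor(l / 2)}`` where ``l = len(word)``; the ``n - 1`` split
    positions are drawn uniformly without replacement from the ``l - 1``
    interior boundaries.  Words with ``floor(l / 2) < 2`` (length <= 3) are
    returned whole.
    """
    if not word:
        raise ValueError("cannot segment the empty string")
    l = len(word)
    n_max = l // 2
    if n_max < 2:
        return [word]
    n = int(rng.integers(2, n_max + 1))
    cuts = np.sort(rng.choice(np.arange(1, l), size=n - 1, replace=False))
    bounds = [0, *cuts.tolist(), l]
    return [word[a:b] for a, b in zip(bounds[:-1], bounds[1:])]


def build_lexicon(
    words: Sequence[str],
    scheme: SegmentationScheme,
    external: Optional[SegmentedLexicon] = None,
) -> SegmentedLexicon:
    """Segment each word under ``scheme`` and collect the result.

    For the random scheme a single generator seeded with ``scheme.seed`` is
    consumed in word order, and each word type is segmented exactly once
    (per-type caching), so the lexicon is reproducible from the seed.
    """
    entries: Dict[str, List[str]] = {}
    rng = np.random.default_rng(scheme.seed) if scheme.name == "random" else None
    for word in words:
        if word in entries:
            continue
        if scheme.name == "whole":
            entries[word] = segment_whole(word)
        elif scheme.name == "ngram":
            entries[word] = segment_ngram(word, scheme.k)  # type: ignore[arg-type]
        elif scheme.name == "random":
            entries[word] = segment_random(word, rng)  # type: ignore[arg-type]
        else:
            if external is None:
                raise ValueError("lexicon scheme requires an external SegmentedLexicon")
            if word not in external:
                raise KeyError(f"word {word!r} absent from external lexicon")
            entries[word] = external.segments_of(word)
    return SegmentedLexicon(entries=entries, scheme=scheme)


def load_segmentation_lexicon(
    path: str | Path,
    check_concatenation: bool = True,
) -> SegmentedLexicon:
    """Read a segmentation lexicon from a TSV file.

    Format: one entry per line, ``word<TAB>seg1 seg2 ...``, UTF-8; lines
    starting with ``#`` are ignored.  ``check_concatenation=False`` skips the
    surface-form check for lexicons whose segments are normalized (lemma-level
    morphs that need not concatenate to the surface form).
    """
    path = Path(path)
    entries: Dict[str, List[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if "\t" not in line:
                raise ValueError(f"{path}:{lineno}: malformed line (no TAB): {line!r}")
            word, seg_field = line.split("\t", 1)
            word = word.strip()
            segments = seg_field.split()
            if not word or not segments:
                raise ValueError(f"{path}:{lineno}: empty word or segments field")
            if word in entries:
                raise ValueError(f"{path}:{lineno}: duplicate word {word!r}")
            if check_concatenation and "".join(segments) != word:
                raise ValueError(
                    f"{path}:{lineno}: segments {segments} do not concatenate to {word!r}"
                )
            entries[word] = segments
    scheme = SegmentationScheme(name="lexicon", source_path=str(path))
    return SegmentedLexicon(entries=entries, scheme=scheme)


def write_segmentation_lexicon(lexicon: SegmentedLexicon, path: str | Path) -> None:
    """Write a lexicon in the TSV format read by :func:`load_segmentation_lexicon`."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# segmentation lexicon, scheme={lexicon.scheme.name}\n")
        for word, segs in lexicon.entries.items():
            fh.write(f"{word}\t{' '.join(segs)}\n")


def segment_corpus_stream(
    tokens: Iterable[str],
    scheme: SegmentationScheme,
    lexicon: Optional[SegmentedLexicon] = None,
    rng: Optional[np.random.Generator] = None,
    _cache: Optional[Dict[str, List[str]]] = None,
) -> Iterator[str]:
    """Replace each token of a stream by its ordered segments.

    Under the lexicon scheme, out-of-lexicon tokens pass through whole and are
    counted in a log message.  The random scheme caches per word type so that
    repeated instances of a word receive the identical segmentation.
    """
    cache: Dict[str, List[str]] = {} if _cache is None else _cache
    if scheme.name == "random" and rng is None:
        rng = np.random.default_rng(scheme.seed)
    n_oov = 0
    for tok in tokens:
        if tok in cache:
            segs = cache[tok]
        elif scheme.name == "whole":
            segs = segment_whole(tok)
        elif scheme.name == "ngram":
            segs = segment_ngram(tok, scheme.k)  # type: ignore[arg-type]
        elif scheme.name == "random":
            segs = segment_random(tok, rng)  # type: ignore[arg-type]
        else:
            if lexicon is not None and tok in lexicon:
                segs = lexicon.segments_of(tok)
            else:
                segs = [tok]
                n_oov += 1
        cache[tok] = segs
        yield from segs
    if n_oov:
        logger.info("segment_corpus_stream: %d out-of-lexicon tokens passed through whole", n_oov)


def _boundaries(segments: Sequence[str]) -> frozenset[int]:
    """Interior boundary positions (cumulative code-point offsets) of a
    segmentation, excluding 0 and the word length."""
    acc = 0
    out = []
    for seg in segments[:-1]:
        acc += len(seg)
        out.append(acc)
    return frozenset(out)


def classify_segmentation(
    statistical: Sequence[str], linguistic: Sequence[str]
) -> str:
    """Label one word's statistical segmentation against the linguistic one.

    Categories:

    - ``identical``: equal segment lists.
    - ``unsegmented``: statistical left the word whole while the linguistic
      analysis splits it.
    - ``incomplete``: the statistical boundaries are a strict subset of the
      linguistic ones (morphs were joined, none invented).
    - ``incorrect_stem`` / ``incorrect_suffix``: at least one statistical
      boundary is not a linguistic boundary; classified ``stem`` if the first
      such offending boundary lies at or before the end of the first
      linguistic segment, else ``suffix``.
    """
    if list(statistical) == list(linguistic):
        return "identical"
    sb = _boundaries(statistical)
    lb = _boundaries(linguistic)
    wrong = sorted(sb - lb)
    if not wrong:
        # every statistical boundary is linguistic
        if len(statistical) == 1 and len(linguistic) > 1:
            return "unsegmented"
        return "incomplete"
    stem_end = len(linguistic[0])
    return "incorrect_stem" if wrong[0] <= stem_end else "incorrect_suffix"


def compare_segmentations(
    statistical: SegmentedLexicon, linguistic: SegmentedLexicon
) -> Tuple[Dict[str, str], Dict[str, int]]:
    """Compare two lexicons word by word.

    Returns ``(per_word_category, category_counts)``.  Both lexicons must
    cover exactly the same words.
    """
    sk, lk = set(statistical.entries), set(linguistic.entries)
    if sk != lk:
        diff = sorted(sk.symmetric_difference(lk))
        raise ValueError(f"lexicons cover different words; symmetric difference: {diff}")
    per_word = {
        w: classify_segmentation(statistical.entries[w], linguistic.entries[w])
        for w in statistical.entries
    }
    counts = Counter(per_word.values())
    return per_word, {cat: counts.get(cat, 0) for cat in COMPARISON_CATEGORIES}


def lexicon_statistics(lexicon: SegmentedLexicon) -> Dict[str, float]:
    """Summary statistics of a lexicon: word count, mean/min/max word length
    (code points), and min/max segments per word."""
    lengths = [len(w) for w in lexicon.entries]
    n_segs = [len(s) for s in lexicon.entries.values()]
    return {
        "n_words": len(lexicon),
        "mean_word_length": float(np.mean(lengths)),
        "min_word_length": int(min(lengths)),
        "max_word_length": int(max(lengths)),
        "min_segments_per_word": int(min(n_segs)),
        "max_segments_per_word": int(max(n_segs)),
    }
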