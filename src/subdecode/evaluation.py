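"""Leave-two-out 2-vs-2 decoding evaluation.

For every unordered pair of words the decoder is fitted on the remaining
``n - 2`` words and the two held-out brain responses are projected into the
word-vector space.  The pair is scored correct (1) when the summed cosine
distances of the matched assignments, ``d(p1, a1) + d(p2, a2)``, are strictly
smaller than the crossed sum ``d(p1, a2) + d(p2, a1)``; incorrect (0) when
strictly larger; exact ties score 0.5 so that accuracy remains an unbiased
mean under degenerate predictors.  Accuracy in a time window is the mean
outcome over pairs.

:class:`PairwiseDecoder` caches the per-fold feature standardization and SVD,
which depend only on the brain data, so that re-evaluating with relabelled or
recomposed word vectors — the permutation tests — costs only small matrix
products per fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .decoding import (
    ALPHA_GRID,
    EpochsArray,
    WindowSpec,
    _standardize_columns,
    _svd_loo_alpha_errors,
    window_slices,
)
from .embedding import WordVectorMatrix, cosine_distance

logger = logging.getLogger(__name__)


def two_vs_two(
    p1: np.ndarray, p2: np.ndarray, a1: np.ndarray, a2: np.ndarray
) -> float:
    """Score one 2-vs-2 trial: 1 if the matched cosine-distance sum beats the
    crossed sum, 0 if it loses, 0.5 on an exact tie."""
    matched = cosine_distance(p1, a1) + cosine_distance(p2, a2)
    crossed = cosine_distance(p1, a2) + cosine_distance(p2, a1)
    if matched < crossed:
        return 1.0
    if matched > crossed:
        return 0.0
    return 0.5


@dataclass
class DecoderConfig:
    """Decoder options shared by the observed run and the permutation runs.

    ``alpha_scope`` controls where the per-dimension regularization search
    happens: ``"per-fold"`` (default) re-tunes inside every leave-two-out
    fold; ``"per-window"`` tunes once per time window on all words and reuses
    those strengths in every fold.  ``zscore`` selects fold-internal
    standardization (default, leakage-free) or a global z-transform over all
    words (``"global"``) for comparison with analyses that standardize before
    cross-validation.
    """

    grid: np.ndarray = field(default_factory=lambda: ALPHA_GRID.copy())
    alpha_cv: str = "loo"
    alpha_scope: str = "per-fold"
    zscore: str = "fold"

    def __post_init__(self) -> None:
        if self.alpha_scope not in ("per-fold", "per-window"):
            raise ValueError(f"unknown alpha_scope {self.alpha_scope!r}")
        if self.zscore not in ("fold", "global"):
            raise ValueError(f"unknown zscore mode {self.zscore!r}")


def make_pairs(
    n: int, max_pairs: Optional[int] = None, seed: Optional[int] = None
) -> Tuple[List[Tuple[int, int]], bool]:
    """All unordered index pairs, optionally subsampled (seeded, without
    replacement) to at most ``max_pairs``.  Returns (pairs, subsampled?)."""
    pairs = list(combinations(range(n), 2))
    if max_pairs is None or max_pairs >= len(pairs):
        return pairs, False
    rng = np.random.default_rng(seed)
    keep = rng.choice(len(pairs), size=max_pairs, replace=False)
    return [pairs[i] for i in sorted(keep)], True


class PairwiseDecoder:
    """Leave-two-out 2-vs-2 engine for one window's feature matrix.

    All quantities that depend only on the features — per-fold column
    statistics, the SVD of the standardized training block, and the projected
    test rows — are precomputed once, so :meth:`evaluate` can be called many
    times with different target matrices (word-label or segment-label
    permutations) at small marginal cost.
    """

    def __init__(
        self,
        X: np.ndarray,
        pairs: Sequence[Tuple[int, int]],
        config: Optional[DecoderConfig] = None,
    ) -> None:
        self.config = config or DecoderConfig()
        X = np.asarray(X, float)
        self.n, self.p = X.shape
        if self.n < 4:
            raise ValueError("need at least 4 words for leave-two-out 2-vs-2")
        self.pairs = list(pairs)
        self._global_X = self.config.zscore == "global"
        if self._global_X:
            Xg, _, _ = _standardize_columns(X)
        self._folds = []
        for i, j in self.pairs:
            mask = np.ones(self.n, bool)
            mask[[i, j]] = False
            if self._global_X:
                Xs_tr, Xs_te = Xg[mask], Xg[[i, j]]
            else:
                Xs_tr, mean, scale = _standardize_columns(X[mask])
                Xs_te = (X[[i, j]] - mean) / scale
            U, s, Vt = np.linalg.svd(Xs_tr, full_matrices=False)
            T = Xs_te @ Vt.T  # (2, r)
            self._folds.append((mask, U, s, T))

    def _window_alphas(self, Y: np.ndarray) -> np.ndarray:
        """Tune per-dimension alphas once on all words (per-window scope).
        Requires :meth:`prepare_full` to have been called with the raw
        feature matrix."""
        if not hasattr(self, "_full_svd"):
            raise RuntimeError("per-window alpha scope requires prepare_full(X)")
        U, s = self._full_svd
        Ys, _, _ = _standardize_columns(Y)
        errs = _svd_loo_alpha_errors(U, s, Ys, self.config.grid)
        return self.config.grid[np.argmin(errs, axis=0)]

    def prepare_full(self, X: np.ndarray) -> None:
        Xs, _, _ = _standardize_columns(np.asarray(X, float))
        U, s, _ = np.linalg.svd(Xs, full_matrices=False)
        self._full_svd = (U, s)

    def evaluate(
        self,
        Y: np.ndarray,
        alphas: Optional[List[np.ndarray]] = None,
        tune: bool = True,
    ) -> Tuple[np.ndarray, List[np.ndarray]]:
        """Score every pair against target matrix ``Y``.

        Parameters
        ----------
        Y
            (n_words, D) word-vector matrix, row-aligned with the features.
        alphas
            Per-fold alpha vectors from a previous call; if given, tuning is
            skipped (the documented fast mode for permutation runs).
        tune
            If False and ``alphas`` is None, per-window alphas are used
            (requires :meth:`prepare_full`).

        Returns
        -------
        outcomes : (n_pairs,) array of {0, 0.5, 1}
        alphas_used : list of per-fold (D,) alpha vectors
        """
        Y = np.asarray(Y, float)
        if Y.shape[0] != self.n:
            raise ValueError("Y row count does not match the feature matrix")
        grid = self.config.grid
        window_alphas = None
        if alphas is None and (not tune or self.config.alpha_scope == "per-window"):
            window_alphas = self._window_alphas(Y)
        if self._global_X:
            Yg, _, _ = _standardize_columns(Y)
        outcomes = np.empty(len(self.pairs))
        alphas_used: List[np.ndarray] = []
        for f, ((i, j), (mask, U, s, T)) in enumerate(zip(self.pairs, self._folds)):
            if self._global_X:
                Ys, y_mean, y_scale = Yg[mask], np.zeros(Y.shape[1]), np.ones(Y.shape[1])
            else:
                Ys, y_mean, y_scale = _standardize_columns(Y[mask])
            if alphas is not None:
                a = alphas[f]
            elif window_alphas is not None:
                a = window_alphas
            else:
                errs = _svd_loo_alpha_errors(U, s, Ys, grid)
                a = grid[np.argmin(errs, axis=0)]
            alphas_used.append(a)
            UtY = U.T @ Ys
            coef = (s[:, None] / (s[:, None] ** 2 + a[None, :])) * UtY
            pred = T @ coef * y_scale + y_mean
            outcomes[f] = two_vs_two(pred[0], pred[1], Y[i], Y[j])
        return outcomes, alphas_used


@dataclass
class DecodingResult:
    """Per-window 2-vs-2 accuracies plus the per-pair outcome table."""

    window_centers: np.ndarray  # seconds
    accuracies: np.ndarray  # in [0, 1], one per window
    outcomes: np.ndarray  # (n_windows, n_pairs) of {0, 0.5, 1}
    pairs: List[Tuple[int, int]]
    words: List[str]
    subsampled: bool
    config: Dict

    def __post_init__(self) -> None:
        if not np.allclose(self.accuracies, self.outcomes.mean(axis=1)):
            raise ValueError("accuracy must equal the mean of per-pair outcomes")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def pair_table(self) -> pd.DataFrame:
        """Long-format (word_i, word_j, window_center_s, outcome) table."""
        rows = []
        for w, center in enumerate(self.window_centers):
            for f, (i, j) in enumerate(self.pairs):
                rows.append((self.words[i], self.words[j], center, self.outcomes[w, f]))
        return pd.DataFrame(rows, columns=["word_i", "word_j", "window_center_s", "outcome"])


def run_two_vs_two(
    epochs: EpochsArray,
    wordvecs: WordVectorMatrix,
    spec: Optional[WindowSpec] = None,
    config: Optional[DecoderConfig] = None,
    max_pairs: Optional[int] = None,
    seed: Optional[int] = None,
) -> DecodingResult:
    """Run the full windowed leave-two-out 2-vs-2 evaluation.

    Word vectors are aligned to the epochs by label; words without any
    covered segment are dropped from the evaluation (and logged), mirroring
    the exclusion of unrepresentable words from decoder training.
    """
    spec = spec or WindowSpec()
    config = config or DecoderConfig()
    missing = [w for w in epochs.words if w not in wordvecs.words]
    if missing:
        raise KeyError(f"epochs words missing from word-vector matrix: {missing}")
    uncovered = set(wordvecs.uncovered_words)
    keep = [w for w in epochs.words if w not in uncovered]
    if len(keep) < len(epochs.words):
        logger.warning(
            "dropping %d words with no covered segments", len(epochs.words) - len(keep)
        )
        epochs = epochs.select_words(keep)
    Y = wordvecs.select(epochs.words).matrix
    pairs, subsampled = make_pairs(epochs.n_words, max_pairs, seed)
    centers, accs, outs = [], [], []
    for center, X in window_slices(epochs, spec):
        engine = PairwiseDecoder(X, pairs, config)
        if config.alpha_scope == "per-window":
            engine.prepare_full(X)
        outcomes, _ = engine.evaluate(Y)
        centers.append(center)
        accs.append(outcomes.mean())
        outs.append(outcomes)
    return DecodingResult(
        window_centers=np.array(centers),
        accuracies=np.array(accs),
        outcomes=np.array(outs),
        pairs=pairs,
        words=list(epochs.words),
        subsampled=subsampled,
        config={
            "window_length_ms": spec.length_ms,
            "window_step_ms": spec.step_ms,
            "alpha_scope": config.alpha_scope,
            "alpha_cv": config.alpha_cv,
            "zscore": config.zscore,
            "max_pairs": max_pairs,
            "pair_seed": seed,
        },
    )


def accuracy_timecourse(result: DecodingResult) -> pd.DataFrame:
    """Tidy (window_center_s, accuracy, n_pairs) table, ordered by time."""
    if len(result.window_centers) == 0:
        raise ValueError("empty decoding result")
    df = pd.DataFrame(
        {
            "window_center_s": result.window_centers,
            "accuracy": result.accuracies,
            "n_pairs": result.n_pairs,
        }
    )
    return df.sort_values("window_center_s", ignore_index=True)
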