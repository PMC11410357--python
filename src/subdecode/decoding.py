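"""Evoked-response container, preprocessing contracts, sliding windows, and
ridge regression with per-target-dimension regularization.

The decoder is a multivariate linear map from windowed sensor features
(``n_sensors x window_samples`` flattened, sensor-major) to the word-vector
space, fitted by ridge regression.  Columns of both the feature matrix and
the target matrix are z-transformed using *training rows only*; a separate
regularization strength is selected for every target dimension from a grid
of 100 log-spaced values between 1e-5 and 1e5, by exact leave-one-out error
(computed via the SVD hat-matrix identity) or, on request, by explicit
leave-two-out cross-validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

logger = logging.getLogger(__name__)

#: 100 logarithmically spaced regularization strengths, endpoints inclusive.
ALPHA_GRID = np.logspace(-5, 5, 100)


@dataclass
class EpochsArray:
    """Item-averaged evoked responses: ``data[word, sensor, time]``.

    ``sfreq`` is the sampling rate in Hz, ``tmin`` the time of the first
    sample in seconds relative to stimulus onset.  Units are fT/cm for real
    gradiometer data, arbitrary for synthetic data.
    """

    data: np.ndarray
    sfreq: float
    tmin: float
    words: List[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"epochs data must be 3-D, got shape {self.data.shape}")
        if len(self.words) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.words)} word labels for {self.data.shape[0]} epochs"
            )
        if len(set(self.words)) != len(self.words):
            raise ValueError("word labels must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epochs data contains non-finite values")

    @property
    def n_words(self) -> int:
        return self.data.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to stimulus onset."""
        return self.tmin + np.arange(self.n_times) / self.sfreq

    def select_words(self, words: Sequence[str]) -> "EpochsArray":
        idx = {w: i for i, w in enumerate(self.words)}
        rows = [idx[w] for w in words]
        return EpochsArray(self.data[rows], self.sfreq, self.tmin, list(words))


def apply_baseline(epochs: EpochsArray) -> EpochsArray:
    """Subtract, per word and sensor, the mean over the pre-stimulus samples
    (times < 0) from the whole epoch.  Idempotent up to numerical noise."""
    pre = epochs.times < 0
    if not np.any(pre):
        raise ValueError("no pre-stimulus samples; cannot baseline-correct")
    base = epochs.data[:, :, pre].mean(axis=2, keepdims=True)
    return EpochsArray(epochs.data - base, epochs.sfreq, epochs.tmin, list(epochs.words))


def reject_epochs(
    epochs: EpochsArray, threshold: float = 3000.0
) -> Tuple[EpochsArray, List[str]]:
    """Drop words whose peak absolute amplitude exceeds ``threshold``
    (default 3000, fT/cm for gradiometer data).  Returns the filtered epochs
    and the list of rejected word labels."""
    if threshold <= 0:
        raise ValueError("rejection threshold must be positive")
    peaks = np.abs(epochs.data).max(axis=(1, 2))
    keep = peaks <= threshold
    rejected = [w for w, k in zip(epochs.words, keep) if not k]
    if not np.any(keep):
        raise ValueError("all epochs exceed the rejection threshold")
    if rejected:
        logger.info("rejected %d epochs above %.0f: %s", len(rejected), threshold, rejected)
    out = EpochsArray(
        epochs.data[keep], epochs.sfreq, epochs.tmin,
        [w for w, k in zip(epochs.words, keep) if k],
    )
    return out, rejected


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry in milliseconds (default 100-ms windows
    advancing by 50 ms, i.e. 50% overlap)."""

    length_ms: float = 100.0
    step_ms: float = 50.0

    def __post_init__(self) -> None:
        if self.length_ms <= 0 or self.step_ms <= 0:
            raise ValueError("window length and step must be positive")
        if self.step_ms > self.length_ms:
            raise ValueError("step must not exceed window length")

    def in_samples(self, sfreq: float) -> Tuple[int, int]:
        """(window, step) in samples; both must be integral at ``sfreq``."""
        length = self.length_ms * sfreq / 1000.0
        step = self.step_ms * sfreq / 1000.0
        if abs(length - round(length)) > 1e-9 or abs(step - round(step)) > 1e-9:
            raise ValueError(
                f"window ({self.length_ms} ms) and step ({self.step_ms} ms) must be "
                f"integral numbers of samples at {sfreq} Hz"
            )
        return int(round(length)), int(round(step))


def window_slices(
    epochs: EpochsArray, spec: WindowSpec
) -> List[Tuple[float, np.ndarray]]:
    """Cut the epoch into overlapping windows and flatten each to a feature
    matrix.

    Windows start at the first sample (``tmin``) and advance by the step
    until a full window no longer fits.  Each feature matrix has shape
    ``(n_words, n_sensors * window_samples)`` with sensor-major layout
    (all samples of sensor 0, then sensor 1, ...).  Returned with each matrix
    is the window's center time in seconds.
    """
    win, step = spec.in_samples(epochs.sfreq)
    if win > epochs.n_times:
        raise ValueError("epoch is shorter than one window")
    out = []
    for start in range(0, epochs.n_times - win + 1, step):
        center = epochs.tmin + (start + win / 2.0) / epochs.sfreq
        X = epochs.data[:, :, start : start + win].reshape(epochs.n_words, -1)
        out.append((center, X))
    return out


def n_windows(n_times: int, win: int, step: int) -> int:
    """Number of full windows: floor((n_times - win) / step) + 1."""
    if win > n_times:
        return 0
    return (n_times - win) // step + 1


# ---------------------------------------------------------------------------
# ridge regression
# ---------------------------------------------------------------------------


def _standardize_columns(M: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column z-transform; constant columns get scale 1 (with a warning) so
    they standardize to zero rather than NaN."""
    mean = M.mean(axis=0)
    scale = M.std(axis=0)
    const = scale == 0
    if np.any(const):
        logger.warning("%d constant columns; their scale is set to 1", int(const.sum()))
        scale = np.where(const, 1.0, scale)
    return (M - mean) / scale, mean, scale


@dataclass
class RidgeMap:
    """Fitted ridge decoder.

    ``weights`` (n_features x D) act on standardized features and produce
    standardized targets; the stored column statistics restore the original
    scales.  ``alphas`` holds the regularization strength selected for each
    target dimension (always members of the grid used at fit time).
    """

    weights: np.ndarray
    alphas: np.ndarray
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: np.ndarray
    y_scale: np.ndarray
    grid: np.ndarray = field(default_factory=lambda: ALPHA_GRID.copy())


def _svd_loo_alpha_errors(
    U: np.ndarray, s: np.ndarray, Ys: np.ndarray, grid: np.ndarray
) -> np.ndarray:
    """Exact leave-one-out squared error for every (alpha, dimension) pair.

    Uses the ridge hat-matrix identity e_loo_i = e_i / (1 - h_i) with
    h_i(alpha) = sum_k U_ik^2 s_k^2 / (s_k^2 + alpha).
    """
    s2 = s**2
    shrink = s2[None, :] / (s2[None, :] + grid[:, None])  # (G, r)
    H = np.clip(U**2 @ shrink.T, None, 1.0 - 1e-12)  # (n, G)
    UtY = U.T @ Ys  # (r, D)
    fitted = np.einsum("nr,gr,rd->ngd", U, shrink, UtY)  # (n, G, D)
    resid = (Ys[:, None, :] - fitted) / (1.0 - H)[:, :, None]
    return np.mean(resid**2, axis=0)  # (G, D)


def _l2o_alpha_errors(
    Xs: np.ndarray, Ys: np.ndarray, grid: np.ndarray
) -> np.ndarray:
    """Explicit leave-two-out squared error for every (alpha, dimension)
    pair: every unordered pair of rows is held out in turn."""
    n = Xs.shape[0]
    errs = np.zeros((len(grid), Ys.shape[1]))
    n_pairs = 0
    for i, j in combinations(range(n), 2):
        mask = np.ones(n, bool)
        mask[[i, j]] = False
        U, s, Vt = np.linalg.svd(Xs[mask], full_matrices=False)
        UtY = U.T @ Ys[mask]
        T = Xs[[i, j]] @ Vt.T  # (2, r)
        for g, alpha in enumerate(grid):
            coef = (s / (s**2 + alpha))[:, None] * UtY
            pred = T @ coef
            errs[g] += np.sum((Ys[[i, j]] - pred) ** 2, axis=0)
        n_pairs += 1
    return errs / (2 * n_pairs)


def fit_ridge(
    X: np.ndarray,
    Y: np.ndarray,
    grid: np.ndarray = ALPHA_GRID,
    alpha_cv: str = "loo",
    alphas: Optional[np.ndarray] = None,
) -> RidgeMap:
    """Fit the ridge decoder with a per-dimension regularization search.

    Parameters
    ----------
    X, Y
        Row-aligned feature and target matrices (>= 4 rows).
    grid
        Candidate regularization strengths.
    alpha_cv
        ``"loo"`` (exact leave-one-out shortcut, default) or ``"l2o"``
        (explicit leave-two-out over the training rows).
    alphas
        If given, skip the search and use these per-dimension strengths.
    """
    X = np.atleast_2d(np.asarray(X, float))
    Y = np.atleast_2d(np.asarray(Y, float))
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    if X.shape[0] < 4:
        raise ValueError(f"need at least 4 training rows, got {X.shape[0]}")
    Xs, x_mean, x_scale = _standardize_columns(X)
    Ys, y_mean, y_scale = _standardize_columns(Y)
    U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    if alphas is None:
        if alpha_cv == "loo":
            errs = _svd_loo_alpha_errors(U, s, Ys, grid)
        elif alpha_cv == "l2o":
            errs = _l2o_alpha_errors(Xs, Ys, grid)
        else:
            raise ValueError(f"unknown alpha_cv {alpha_cv!r}")
        alphas = grid[np.argmin(errs, axis=0)]
    else:
        alphas = np.asarray(alphas, float)
        if alphas.shape != (Y.shape[1],):
            raise ValueError("alphas must have one entry per target dimension")
    UtY = U.T @ Ys
    coef = (s[:, None] / (s[:, None] ** 2 + alphas[None, :])) * UtY
    weights = Vt.T @ coef
    return RidgeMap(weights, alphas, x_mean, x_scale, y_mean, y_scale, np.asarray(grid))


def predict(rmap: RidgeMap, X_test: np.ndarray) -> np.ndarray:
    """Apply a fitted decoder: standardize the test features with the
    *training* statistics, map, and de-standardize back to the original
    target scale."""
    X_test = np.atleast_2d(np.asarray(X_test, float))
    if X_test.shape[1] != rmap.x_mean.shape[0]:
        raise ValueError(
            f"feature mismatch: map expects {rmap.x_mean.shape[0]}, got {X_test.shape[1]}"
        )
    Xs = (X_test - rmap.x_mean) / rmap.x_scale
    return Xs @ rmap.weights * rmap.y_scale + rmap.y_mean
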