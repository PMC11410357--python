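"""Word-label and segment-label permutation nulls: conservation, coupling to
the observed run, reproducibility, and decision rules."""

import numpy as np
import pytest

from subdecode.decoding import EpochsArray, WindowSpec
from subdecode.embedding import SegmentVectorStore, WordVectorMatrix, compose_word_vectors
from subdecode.evaluation import PairwiseDecoder, make_pairs
from subdecode.permutation import (
    empirical_threshold,
    permute_segment_store,
    segment_label_null,
    threshold_and_decide,
    word_label_null,
    word_label_null_timecourse,
)
from subdecode.segmentation import SegmentationScheme, SegmentedLexicon

LEX_SCHEME = SegmentationScheme(name="lexicon", source_path="x")


def make_wv(X):
    words = [f"w{i}" for i in range(X.shape[0])]
    return WordVectorMatrix(words, np.asarray(X, float),
                            {w: {"found": ["x"], "missing": []} for w in words})


def noise_epochs(rng, n=10, sensors=4, times=100, sfreq=100.0):
    return EpochsArray(rng.standard_normal((n, sensors, times)), sfreq, -0.2,
                       [f"w{i}" for i in range(n)])


class TestDecisionRules:
    def test_observed_above_all_nulls(self):
        null = np.linspace(0.4, 0.6, 99)
        d = threshold_and_decide(0.9, null)
        assert d["significant"] and d["p_value"] == pytest.approx(1 / 100)

    def test_observed_at_median_not_significant(self):
        null = np.linspace(0.3, 0.7, 101)
        d = threshold_and_decide(float(np.median(null)), null)
        assert not d["significant"]

    def test_level_half_is_median(self, rng):
        null = rng.random(101)
        assert empirical_threshold(null, 0.5) == pytest.approx(np.median(null))

    def test_nearest_rank_method(self):
        null = np.arange(1, 101) / 100.0
        thr = empirical_threshold(null, 0.95, method="nearest-rank")
        assert thr in null

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            empirical_threshold(np.array([]))


class TestPermuteStore:
    def _store(self, rng, labels):
        return SegmentVectorStore({l: rng.standard_normal(3) for l in labels}, 3)

    def test_vector_multiset_preserved(self, rng):
        store = self._store(rng, list("abcdef"))
        perm = permute_segment_store(store, 0)
        before = np.sort(np.stack(list(store.vectors.values())), axis=0)
        after = np.sort(np.stack(list(perm.vectors.values())), axis=0)
        np.testing.assert_array_equal(before, after)

    def test_restriction_leaves_outside_labels_untouched(self, rng):
        store = self._store(rng, list("abcd"))
        perm = permute_segment_store(store, 0, restrict_to=["a", "b"])
        np.testing.assert_array_equal(perm["c"], store["c"])
        np.testing.assert_array_equal(perm["d"], store["d"])

    def test_two_segments_identity_or_swap_half_half(self, rng):
        store = self._store(rng, ["a", "b"])
        swaps = 0
        n = 400
        for seed in range(n):
            perm = permute_segment_store(store, seed)
            if np.array_equal(perm["a"], store["b"]):
                swaps += 1
        # binomial(400, 1/2): 3 sigma band is 200 +/- 30
        assert abs(swaps - n / 2) < 3 * np.sqrt(n) / 2

    def test_fewer_than_two_errors(self, rng):
        store = self._store(rng, ["a"])
        with pytest.raises(ValueError):
            permute_segment_store(store, 0)

    def test_shared_segment_structure_preserved(self, rng):
        """Words sharing a segment before the shuffle still share one vector
        term after it: the difference of their composed vectors equals the
        difference of the unshared segments' permuted vectors."""
        store = self._store(rng, ["stem", "x", "y"])
        lex = SegmentedLexicon({"sx": ["stem", "x"], "sy": ["stem", "y"]}, LEX_SCHEME)
        perm = permute_segment_store(store, 5)
        wv = compose_word_vectors(lex, perm, ["sx", "sy"])
        np.testing.assert_allclose(wv.matrix[0] - wv.matrix[1], perm["x"] - perm["y"])


class TestWordLabelNull:
    def test_identity_permutation_reproduces_observed(self, rng):
        X = rng.standard_normal((8, 6))
        Y = rng.standard_normal((8, 3))
        pairs, _ = make_pairs(8)
        engine = PairwiseDecoder(X, pairs)
        obs, alphas = engine.evaluate(Y)
        again, _ = engine.evaluate(Y[np.arange(8)], alphas=alphas)
        np.testing.assert_array_equal(obs, again)

    def test_reproducible_bit_for_bit(self, rng):
        ep = noise_epochs(rng)
        wv = make_wv(rng.standard_normal((10, 3)))
        r1 = word_label_null(ep, wv, n_perm=20, seed=9, at_time=0.2)
        r2 = word_label_null(ep, wv, n_perm=20, seed=9, at_time=0.2)
        np.testing.assert_array_equal(r1.null, r2.null)
        assert r1.observed == r2.observed

    def test_null_mean_near_chance(self, rng):
        ep = noise_epochs(rng, n=12)
        wv = make_wv(rng.standard_normal((12, 3)))
        res = word_label_null(ep, wv, n_perm=100, seed=1, at_time=0.2)
        se = res.null.std(ddof=1) / np.sqrt(len(res.null))
        assert abs(res.null.mean() - 0.5) < max(3 * se, 0.05)

    def test_p_value_definition(self, rng):
        ep = noise_epochs(rng, n=8)
        wv = make_wv(rng.standard_normal((8, 3)))
        res = word_label_null(ep, wv, n_perm=19, seed=2, at_time=0.2)
        expected = (1 + np.sum(res.null >= res.observed)) / 20
        assert res.p_value == pytest.approx(expected)

    def test_timecourse_shares_permutations_across_windows(self, rng):
        ep = noise_epochs(rng, n=8, times=20)
        wv = make_wv(rng.standard_normal((8, 3)))
        tc = word_label_null_timecourse(ep, wv, WindowSpec(100, 100), n_perm=10, seed=4)
        assert tc.null.shape == (10, 2)
        assert tc.thresholds.shape == (2,)
        # same seed reproduces
        tc2 = word_label_null_timecourse(ep, wv, WindowSpec(100, 100), n_perm=10, seed=4)
        np.testing.assert_array_equal(tc.null, tc2.null)


class TestSegmentLabelNull:
    def test_identity_bijection_reproduces_observed(self, rng):
        """The observed accuracy reported by the null run equals a direct
        evaluation of the unpermuted composition."""
        n = 8
        ep = noise_epochs(rng, n=n)
        labels = [f"s{i}" for i in range(n)]
        store = SegmentVectorStore({l: rng.standard_normal(3) for l in labels}, 3)
        lex = SegmentedLexicon({w: [l] for w, l in zip(ep.words, labels)}, LEX_SCHEME)
        res = segment_label_null(ep, lex, store, n_perm=5, seed=0, at_time=0.2)
        wv = compose_word_vectors(lex, store, ep.words)
        ref = word_label_null(ep, wv, n_perm=1, seed=0, at_time=0.2)
        assert res.observed == pytest.approx(ref.observed)

    def test_unique_singleton_segments_equal_word_label_null(self, rng):
        """When every word is one unique segment, permuting segment labels is
        the same construction as permuting word labels: identical nulls."""
        n = 8
        ep = noise_epochs(rng, n=n)
        labels = [f"s{i}" for i in range(n)]
        store = SegmentVectorStore({l: rng.standard_normal(3) for l in labels}, 3)
        lex = SegmentedLexicon({w: [l] for w, l in zip(ep.words, labels)}, LEX_SCHEME)
        seg = segment_label_null(ep, lex, store, n_perm=30, seed=11, at_time=0.2)
        wv = compose_word_vectors(lex, store, ep.words)
        word = word_label_null(ep, wv, n_perm=30, seed=11, at_time=0.2)
        np.testing.assert_allclose(seg.null, word.null)

    def test_occurrence_pattern_invariant(self, rng):
        """The words x segments occurrence matrix is unchanged by the
        permutation; only the vector attached to each column moves."""
        from subdecode.permutation import _occurrence_matrix

        lex = SegmentedLexicon(
            {"ax": ["a", "x"], "ay": ["a", "y"], "bx": ["b", "x"]}, LEX_SCHEME
        )
        labels = ["a", "b", "x", "y"]
        C = _occurrence_matrix(lex, ["ax", "ay", "bx"], labels)
        np.testing.assert_array_equal(
            C, [[1, 0, 1, 0], [1, 0, 0, 1], [0, 1, 1, 0]]
        )

    def test_shared_suffix_inflates_segment_null(self, rng):
        """With heavy segment sharing the segment-label null sits above the
        word-label null (the diagnostic the test exists for)."""
        from subdecode.synthetic import SyntheticConfig, make_dataset
        from subdecode.decoding import apply_baseline
        from subdecode.segmentation import build_lexicon

        cfg = SyntheticConfig(n_stems=8, n_suffixes=2, dim=10, n_sensors=6,
                              sfreq=100.0, snr=5.0, seed=3)
        epochs, truth = make_dataset(cfg)
        ep = apply_baseline(epochs)
        uni = build_lexicon(truth.words, SegmentationScheme(name="ngram", k=1))
        chars = uni.segment_types()
        store = SegmentVectorStore({c: rng.standard_normal(10) for c in chars}, 10)
        seg = segment_label_null(ep, uni, store, n_perm=40, seed=5, at_time=0.425)
        wv = compose_word_vectors(uni, store, truth.words)
        word = word_label_null(ep, wv, n_perm=40, seed=5, at_time=0.425)
        assert seg.null.mean() > word.null.mean() + 0.05

    def test_fewer_than_two_segments_errors(self, rng):
        ep = noise_epochs(rng, n=4)
        lex = SegmentedLexicon({w: ["only"] for w in ep.words}, LEX_SCHEME)
        store = SegmentVectorStore({"only": rng.standard_normal(3)}, 3)
        with pytest.raises(ValueError):
            segment_label_null(ep, lex, store, n_perm=2, seed=0)
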