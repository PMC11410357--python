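"""Segment vectors: composition by summation, cosine utilities,
complete-linkage clustering, word2vec text IO, and the skip-gram trainer's
distributional property."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from subdecode.embedding import (
    EmbeddingConfig,
    SegmentVectorStore,
    WordVectorMatrix,
    cluster_words,
    compose_word_vectors,
    cosine_distance,
    dendrogram_to_newick,
    read_vectors,
    train_segment_vectors,
    write_vectors,
)
from subdecode.segmentation import SegmentationScheme, SegmentedLexicon, build_lexicon

LEX_SCHEME = SegmentationScheme(name="lexicon", source_path="x")


def make_store(d, **vecs):
    return SegmentVectorStore({k: np.asarray(v, float) for k, v in vecs.items()}, d)


class TestCompose:
    def test_summation_examples(self):
        store = make_store(2, a=(1, 0), b=(0, 1))
        lex = SegmentedLexicon({"ab": ["a", "b"], "a": ["a"]}, LEX_SCHEME)
        wv = compose_word_vectors(lex, store, ["ab", "a"])
        np.testing.assert_array_equal(wv.matrix[0], [1, 1])
        np.testing.assert_array_equal(wv.matrix[1], [1, 0])

    def test_multiplicity(self):
        store = make_store(2, a=(1, 0), b=(0, 2))
        lex = SegmentedLexicon({"aba": ["a", "b", "a"]}, LEX_SCHEME)
        wv = compose_word_vectors(lex, store, ["aba"])
        np.testing.assert_array_equal(wv.matrix[0], [2, 2])

    def test_missing_segment_recorded_and_uncovered_listed(self):
        store = make_store(2, a=(1, 0))
        lex = SegmentedLexicon({"ab": ["a", "b"], "cc": ["c", "c"]}, LEX_SCHEME)
        wv = compose_word_vectors(lex, store, ["ab", "cc"])
        assert wv.coverage["ab"]["missing"] == ["b"]
        assert wv.uncovered_words == ["cc"]
        np.testing.assert_array_equal(wv.matrix[1], [0, 0])

    def test_word_absent_from_lexicon(self):
        store = make_store(1, a=(1,))
        lex = SegmentedLexicon({"a": ["a"]}, LEX_SCHEME)
        with pytest.raises(KeyError):
            compose_word_vectors(lex, store, ["zzz"])

    def test_linearity_over_stores(self, rng):
        """compose under s1 plus compose under s2 equals compose under the
        summed store (summation composition is linear)."""
        labels = list("abcd")
        v1 = {l: rng.standard_normal(3) for l in labels}
        v2 = {l: rng.standard_normal(3) for l in labels}
        s1 = SegmentVectorStore(dict(v1), 3)
        s2 = SegmentVectorStore(dict(v2), 3)
        s12 = SegmentVectorStore({l: v1[l] + v2[l] for l in labels}, 3)
        lex = SegmentedLexicon({"abc": ["a", "b", "c"], "dd": ["d", "d"]}, LEX_SCHEME)
        words = ["abc", "dd"]
        m1 = compose_word_vectors(lex, s1, words).matrix
        m2 = compose_word_vectors(lex, s2, words).matrix
        m12 = compose_word_vectors(lex, s12, words).matrix
        np.testing.assert_allclose(m1 + m2, m12, atol=1e-12)

    def test_whole_word_equals_lookup(self, rng):
        words = ["talo", "kirja"]
        store = SegmentVectorStore({w: rng.standard_normal(4) for w in words}, 4)
        lex = build_lexicon(words, SegmentationScheme(name="whole"))
        wv = compose_word_vectors(lex, store, words)
        for i, w in enumerate(words):
            np.testing.assert_array_equal(wv.matrix[i], store[w])


class TestCosine:
    def test_examples(self):
        assert cosine_distance([1, 1], [1, 1]) == pytest.approx(0.0)
        assert cosine_distance([1, 0], [0, 1]) == pytest.approx(1.0)
        assert cosine_distance([1, 1], [1, 0]) == pytest.approx(1 - 1 / np.sqrt(2))

    def test_zero_vector_and_mismatch(self):
        with pytest.raises(ValueError):
            cosine_distance([0, 0], [1, 0])
        with pytest.raises(ValueError):
            cosine_distance([1, 0], [1, 0, 0])

    @given(
        u=st.lists(st.floats(-10, 10), min_size=3, max_size=3),
        v=st.lists(st.floats(-10, 10), min_size=3, max_size=3),
        c=st.floats(0.01, 100),
    )
    @settings(max_examples=100, deadline=None)
    def test_symmetry_and_positive_scale_invariance(self, u, v, c):
        u, v = np.asarray(u), np.asarray(v)
        if np.linalg.norm(u) < 1e-6 or np.linalg.norm(v) < 1e-6:
            return
        d = cosine_distance(u, v)
        assert 0 <= d <= 2
        assert d == pytest.approx(cosine_distance(v, u))
        assert d == pytest.approx(cosine_distance(c * u, v), abs=1e-9)


def _naive_complete_linkage_heights(D):
    """O(n^3) complete linkage on a square distance matrix; returns sorted
    merge heights."""
    n = D.shape[0]
    clusters = [[i] for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = (np.inf, None)
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                h = max(D[i, j] for i in clusters[a] for j in clusters[b])
                if h < best[0]:
                    best = (h, (a, b))
        h, (a, b) = best
        heights.append(h)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return sorted(heights)


class TestClustering:
    def _wv(self, X):
        X = np.asarray(X, float)
        words = [f"w{i}" for i in range(X.shape[0])]
        return WordVectorMatrix(words, X,
                                {w: {"found": ["x"], "missing": []} for w in words})

    def test_identical_rows_merge_at_zero(self):
        Z = cluster_words(self._wv([[1, 2], [1, 2], [5, -1]]))
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_outlier_merges_last(self):
        X = np.array([[1.0, 0.05], [1.0, -0.05], [-1.0, 0.0]])
        Z = cluster_words(self._wv(X))
        # first merge joins the two close points; the outlier joins last
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}
        assert {int(Z[-1, 0]), int(Z[-1, 1])} == {2, 3}

    def test_zero_row_rejected(self):
        with pytest.raises(ValueError):
            cluster_words(self._wv([[0, 0], [1, 2]]))

    def test_monotone_merge_heights(self, rng):
        Z = cluster_words(self._wv(rng.standard_normal((10, 4))))
        assert np.all(np.diff(Z[:, 2]) >= -1e-12)

    def test_against_naive_oracle_six_points(self, rng):
        X = rng.standard_normal((6, 3))
        Z = cluster_words(self._wv(X))
        norm = X / np.linalg.norm(X, axis=1, keepdims=True)
        D = 1 - norm @ norm.T
        np.fill_diagonal(D, 0)
        np.testing.assert_allclose(sorted(Z[:, 2]), _naive_complete_linkage_heights(D),
                                   atol=1e-10)

    def test_newick_parsed_by_independent_library(self, rng):
        dendropy = pytest.importorskip("dendropy")
        X = rng.standard_normal((5, 3))
        wv = self._wv(X)
        Z = cluster_words(wv)
        nwk = dendrogram_to_newick(Z, wv.words)
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        # leaf depth from root equals the root merge height for every leaf
        root_height = Z[-1, 2]
        depths = [leaf.distance_from_root() for leaf in tree.leaf_node_iter()]
        np.testing.assert_allclose(depths, root_height, atol=1e-5)


class TestVecIO:
    def test_round_trip(self, tmp_path, rng):
        store = SegmentVectorStore({f"s{i}": rng.standard_normal(3) for i in range(4)}, 3)
        p = tmp_path / "v.vec"
        write_vectors(store, p)
        assert p.read_text(encoding="utf-8").splitlines()[0] == "4 3"
        back = read_vectors(p)
        assert back.dim == 3 and back.labels == store.labels
        for l in store.labels:
            np.testing.assert_array_equal(back[l], store[l])

    def test_header_count_mismatch(self, tmp_path):
        p = tmp_path / "bad.vec"
        p.write_text("2 2\na 1.0 2.0\n", encoding="utf-8")
        with pytest.raises(ValueError, match="header"):
            read_vectors(p)

    def test_dimension_mismatch(self, tmp_path):
        p = tmp_path / "bad.vec"
        p.write_text("1 3\na 1.0 2.0\n", encoding="utf-8")
        with pytest.raises(ValueError):
            read_vectors(p)


class TestSkipgram:
    def _toy_corpus(self):
        sents = []
        for _ in range(150):
            sents.append(["ctxa", "A", "ctxb"])
            sents.append(["ctxa", "B", "ctxb"])
            sents.append(["zzza", "C", "zzzb"])
        return sents

    def test_shared_context_segments_are_closer(self):
        """A and B share all contexts, C none: d(A,B) < d(A,C)."""
        cfg = EmbeddingConfig(dim=16, context_window=2, min_count=5, epochs=10, seed=0)
        store = train_segment_vectors(self._toy_corpus(), cfg)
        assert cosine_distance(store["A"], store["B"]) < cosine_distance(store["A"], store["C"])

    def test_min_count_threshold(self):
        sents = [["a", "b"]] * 10 + [["a", "rare"]] * 4
        cfg = EmbeddingConfig(dim=4, context_window=2, min_count=5, epochs=1, seed=0)
        store = train_segment_vectors(sents, cfg)
        assert "rare" not in store and "a" in store

    def test_exclusion_covering_all_sentences_errors(self):
        sents = [["a", "b"], ["b", "a"]]
        cfg = EmbeddingConfig(
            dim=4, context_window=2, min_count=1, exclude_sentences_containing={"a"}
        )
        with pytest.raises(ValueError):
            train_segment_vectors(sents, cfg)

    def test_exclusion_drops_only_matching_sentences(self):
        sents = [["a", "b"]] * 6 + [["c", "d"]] * 6
        cfg = EmbeddingConfig(
            dim=4, context_window=2, min_count=5, epochs=1,
            exclude_sentences_containing={"a"}, seed=0,
        )
        store = train_segment_vectors(sents, cfg)
        assert set(store.labels) == {"c", "d"}

    def test_config_validation(self):
        with pytest.raises(ValueError):
            EmbeddingConfig(dim=0)
        with pytest.raises(ValueError):
            EmbeddingConfig(training_mode="cbow")
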