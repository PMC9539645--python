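"""Two-layer ensemble: stacking, projection, inspection, model selection."""

import numpy as np
import pytest

from resdict.embedding import WordEmbedding
from resdict.matrices import DocTermMatrix, Vocabulary
from resdict.synthetic import cluster_embedding, planted_profile_matrix
from resdict.topic_ensemble import (
    BaseTopicModel,
    StackedTopicTermMatrix,
    build_document_block,
    fit_base_layer,
    fit_ensemble,
    project_documents,
    select_k_prime,
    stack_base_topics,
    top_posts,
    top_terms,
    topic_coherence,
)
import scipy.sparse as sp


def _dtm(window, n, m, seed):
    rng = np.random.default_rng(seed)
    return DocTermMatrix(
        window_id=window,
        post_ids=tuple(f"{window}-p{i}" for i in range(n)),
        matrix=sp.csr_matrix(rng.random((n, m))),
    )


def _base_model(window, W, H):
    return BaseTopicModel(window_id=window, post_ids=tuple(
        f"{window}-p{i}" for i in range(W.shape[0])
    ), W=W, H=H, k=H.shape[0])


class TestBaseLayer:
    def test_single_window(self):
        models = fit_base_layer({"2018-Q3": _dtm("2018-Q3", 8, 10, 0)}, k=3, seed=0)
        assert len(models) == 1
        assert models[0].k == 3
        assert models[0].H.shape == (3, 10)

    def test_ten_windows_k_ten_yield_hundred_base_topics(self):
        matrices = {
            f"2018-Q{q}" if q <= 4 else f"2019-Q{q-4}": _dtm(f"w{q}", 12, 15, q)
            for q in range(1, 11)
        }
        models = fit_base_layer(matrices, k=10, seed=0)
        stacked = stack_base_topics(models)
        assert stacked.B.shape[0] == 100

    def test_window_named_in_error(self):
        with pytest.raises(ValueError, match="2018-Q3"):
            fit_base_layer({"2018-Q3": _dtm("2018-Q3", 3, 4, 0)}, k=9, seed=0)

    def test_error_traces_non_increasing(self, fitted_pipeline):
        for model in fitted_pipeline["models"]:
            assert (np.diff(model.error_trace) <= 1e-10).all()


class TestStacking:
    def test_row_count_and_copy_semantics(self):
        rng = np.random.default_rng(0)
        models = [
            _base_model("2018-Q3", rng.random((4, 3)), rng.random((3, 7))),
            _base_model("2018-Q4", rng.random((5, 3)), rng.random((3, 7))),
        ]
        stacked = stack_base_topics(models)
        assert stacked.B.shape == (6, 7)
        for q, model in enumerate(models):
            for j in range(3):
                assert (stacked.B[q * 3 + j] == model.H[j]).all()
                assert stacked.row_origin[q * 3 + j] == (model.window_id, j)

    def test_column_mismatch_rejected(self):
        rng = np.random.default_rng(0)
        models = [
            _base_model("a", rng.random((2, 2)), rng.random((2, 5))),
            _base_model("b", rng.random((2, 2)), rng.random((2, 6))),
        ]
        with pytest.raises(ValueError):
            stack_base_topics(models)


class TestEnsemble:
    def test_repeated_profiles_are_recovered(self):
        """When every window has the same H, the ensemble topics at k'=k
        reproduce the shared topics (equal top-term sets)."""
        stacked, vocab = planted_profile_matrix(
            n_profiles=3, reps=4, support_size=10, noise=0.0, seed=0
        )
        ensemble = fit_ensemble(stacked, 3, seed=0)
        planted = [
            set(vocab.terms[i * 10:(i + 1) * 10][:5]) for i in range(3)
        ]
        fitted = [set(top_terms(ensemble, t, 5, vocab)) for t in range(3)]
        for p in planted:
            assert p in fitted

    def test_rank_one_stack(self):
        row = np.abs(np.random.default_rng(0).random(12)) + 0.1
        B = np.vstack([row * s for s in (1.0, 2.0, 0.5)])
        ensemble = fit_ensemble(B, 1, seed=0)
        approx = ensemble.Wp @ ensemble.Hp
        assert np.linalg.norm(B - approx) / np.linalg.norm(B) < 1e-4

    def test_topic_rows_sum_to_one(self, fitted_pipeline):
        sums = fitted_pipeline["ensemble"].Hp.sum(axis=1)
        assert sums == pytest.approx(np.ones(len(sums)), abs=1e-9)


class TestDocumentBlock:
    def test_single_window_equals_W(self):
        rng = np.random.default_rng(1)
        model = _base_model("2018-Q3", rng.random((5, 2)), rng.random((2, 6)))
        C = build_document_block([model])
        assert (C.D == model.W).all()
        assert C.post_ids == model.post_ids

    def test_block_zeros_outside_own_window(self):
        rng = np.random.default_rng(2)
        models = [
            _base_model(f"w{q}", rng.random((3, 2)), rng.random((2, 6)))
            for q in range(3)
        ]
        C = build_document_block(models)
        row = C.D[3]  # first post of window 2 (index 1)
        assert (row[0:2] == 0).all() and (row[4:6] == 0).all()
        assert (row[2:4] == models[1].W[0]).all()

    def test_hand_assembled_two_window_toy(self):
        W1 = np.array([[0.3], [0.7]])
        W2 = np.array([[0.5], [0.1]])
        H = np.array([[0.5, 0.5]])
        models = [_base_model("a", W1, H), _base_model("b", W2, H)]
        C = build_document_block(models)
        expected = np.array([
            [0.3, 0.0],
            [0.7, 0.0],
            [0.0, 0.5],
            [0.0, 0.1],
        ])
        assert C.D == pytest.approx(expected)

    def test_duplicate_post_rejected(self):
        rng = np.random.default_rng(3)
        model = _base_model("a", rng.random((2, 1)), rng.random((1, 4)))
        dup = BaseTopicModel(window_id="b", post_ids=model.post_ids,
                             W=model.W, H=model.H, k=1)
        with pytest.raises(ValueError, match="more than one window"):
            build_document_block([model, dup])


class TestProjection:
    def test_matches_hand_computed_product(self):
        C_mat = np.array([[1.0, 0.0], [0.5, 0.5], [0.0, 2.0], [0.25, 0.75]])
        Wp = np.array([[0.9, 0.1], [0.2, 0.8]])
        rng_models = build_document_block([
            _base_model("a", C_mat[:2, :1], np.ones((1, 3)) / 3),
        ])
        from resdict.topic_ensemble import DocumentEnsembleMatrix, EnsembleTopicModel

        C = DocumentEnsembleMatrix(D=C_mat, post_ids=("p0", "p1", "p2", "p3"),
                                   windows=("a", "a", "b", "b"))
        ensemble = EnsembleTopicModel(Wp=Wp, Hp=np.ones((2, 3)) / 3, k_prime=2,
                                      row_origin=(("a", 0), ("b", 0)))
        D = project_documents(C, ensemble)
        assert D.D == pytest.approx(C_mat @ Wp, abs=1e-10)
        assert (D.D >= 0).all()

    def test_dimension_mismatch_rejected(self):
        from resdict.topic_ensemble import DocumentEnsembleMatrix, EnsembleTopicModel

        C = DocumentEnsembleMatrix(D=np.ones((2, 3)), post_ids=("a", "b"),
                                   windows=("w", "w"))
        ensemble = EnsembleTopicModel(Wp=np.ones((2, 2)), Hp=np.ones((2, 4)),
                                      k_prime=2, row_origin=(("w", 0), ("w", 1)))
        with pytest.raises(ValueError):
            project_documents(C, ensemble)


class TestTopicInspection:
    def _ensemble(self, Hp):
        from resdict.topic_ensemble import EnsembleTopicModel

        return EnsembleTopicModel(
            Wp=np.ones((2, Hp.shape[0])), Hp=np.asarray(Hp, dtype=float),
            k_prime=Hp.shape[0],
            row_origin=tuple(("w", i) for i in range(2)),
        )

    def test_one_hot_topic(self):
        vocab = Vocabulary(terms=("a", "b", "c"))
        ensemble = self._ensemble(np.array([[0.0, 1.0, 0.0]]))
        assert top_terms(ensemble, 0, 1, vocab) == ["b"]

    def test_ordering_matches_sort_oracle(self):
        vocab = Vocabulary(terms=("a", "b", "c"))
        ensemble = self._ensemble(np.array([[0.2, 0.5, 0.3]]))
        weights = {"a": 0.2, "b": 0.5, "c": 0.3}
        oracle = sorted(weights, key=lambda t: (-weights[t], t))
        assert top_terms(ensemble, 0, 3, vocab) == oracle

    def test_ties_broken_lexicographically_and_truncation(self):
        vocab = Vocabulary(terms=("z", "y", "x"))
        ensemble = self._ensemble(np.array([[0.5, 0.5, 0.5]]))
        assert top_terms(ensemble, 0, 99, vocab) == ["x", "y", "z"]

    def test_top_posts_sort_oracle_and_truncation(self):
        from resdict.topic_ensemble import DocumentEnsembleMatrix

        D = DocumentEnsembleMatrix(
            D=np.array([[0.1], [0.9], [0.9], [0.4]]),
            post_ids=("p0", "p1", "p2", "p3"),
            windows=("w",) * 4,
        )
        assert top_posts(D, 0, 3) == ["p1", "p2", "p3"]  # tie kept in corpus order
        assert top_posts(D, 0, 99) == ["p1", "p2", "p3", "p0"]

    def test_single_post_corpus(self):
        from resdict.topic_ensemble import DocumentEnsembleMatrix

        D = DocumentEnsembleMatrix(D=np.array([[0.3, 0.7]]), post_ids=("only",),
                                   windows=("w",))
        assert top_posts(D, 0, 5) == ["only"]
        assert top_posts(D, 1, 5) == ["only"]


class TestCoherence:
    def test_identical_vectors_score_one(self):
        emb = WordEmbedding(terms=("a", "b", "c"),
                            vectors=np.tile([1.0, 2.0], (3, 1)))
        assert topic_coherence(["a", "b", "c"], emb) == pytest.approx(1.0)

    def test_orthogonal_vectors_score_zero(self):
        emb = WordEmbedding(terms=("a", "b"),
                            vectors=np.array([[1.0, 0.0], [0.0, 1.0]]))
        assert topic_coherence(["a", "b"], emb) == pytest.approx(0.0)

    def test_matches_pairwise_enumeration_oracle(self):
        rng = np.random.default_rng(4)
        vectors = rng.standard_normal((4, 6))
        emb = WordEmbedding(terms=("a", "b", "c", "d"), vectors=vectors)
        terms = ["a", "b", "c", "d"]
        sims = []
        for i in range(4):
            for j in range(i + 1, 4):
                u, v = vectors[i], vectors[j]
                sims.append(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))
        assert topic_coherence(terms, emb) == pytest.approx(np.mean(sims))

    def test_too_few_embeddable_terms_warns_and_scores_zero(self):
        emb = WordEmbedding(terms=("a",), vectors=np.ones((1, 2)))
        with pytest.warns(UserWarning):
            assert topic_coherence(["a", "missing"], emb) == 0.0

    def test_missing_terms_skipped(self):
        emb = WordEmbedding(terms=("a", "b"), vectors=np.ones((2, 2)))
        assert topic_coherence(["a", "b", "zzz"], emb) == pytest.approx(1.0)


class TestSelectKPrime:
    def test_degenerate_range(self):
        stacked, vocab = planted_profile_matrix(n_profiles=3, reps=2,
                                                support_size=8, seed=0)
        emb = cluster_embedding(vocab, cluster_size=8, seed=0)
        report = select_k_prime(stacked, [4], emb, vocab, seed=0)
        assert report.chosen == 4
        assert set(report.scores) == {4}

    def test_report_covers_every_candidate(self):
        stacked, vocab = planted_profile_matrix(n_profiles=4, reps=2,
                                                support_size=10, seed=1)
        emb = cluster_embedding(vocab, cluster_size=10, seed=1)
        report = select_k_prime(stacked, range(2, 7), emb, vocab, seed=1)
        assert set(report.scores) | set(report.failures) == set(range(2, 7))

    def test_planted_profile_count_is_chosen(self):
        stacked, vocab = planted_profile_matrix(n_profiles=5, reps=4,
                                                support_size=40, seed=0)
        emb = cluster_embedding(vocab, cluster_size=40, seed=0)
        report = select_k_prime(stacked, range(2, 9), emb, vocab, seed=0)
        assert report.chosen == 5

    def test_failed_candidates_recorded(self):
        stacked, vocab = planted_profile_matrix(n_profiles=3, reps=2,
                                                support_size=8, seed=0)
        emb = cluster_embedding(vocab, cluster_size=8, seed=0)
        # 3 profiles x 2 reps -> only 6 rows; k'=7 cannot be fitted
        report = select_k_prime(stacked, [3, 7], emb, vocab, seed=0)
        assert report.chosen == 3
        assert 7 in report.failures
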