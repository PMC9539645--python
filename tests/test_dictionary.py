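"""Phase 4b: topic weights, synonyms and dictionary assembly."""

import json

import numpy as np
import pytest

from resdict.annotation import TopicIndicatorMap, annotate
from resdict.dictionary import assemble_dictionary, synonyms, topic_weights
from resdict.matrices import Vocabulary
from resdict.taxonomy import collect_post_sets, infer_taxonomy
from resdict.topic_ensemble import DocumentEnsembleMatrix, EnsembleTopicModel


def _D(rows, windows=None):
    rows = np.asarray(rows, dtype=float)
    return DocumentEnsembleMatrix(
        D=rows,
        post_ids=tuple(f"p{i}" for i in range(rows.shape[0])),
        windows=tuple(windows or ["2018-Q3"] * rows.shape[0]),
    )


class TestTopicWeights:
    def test_single_topic_is_hundred(self):
        assert topic_weights(_D([[0.4], [0.9]])) == {0: pytest.approx(100.0)}

    def test_two_post_direct_ratio(self):
        weights = topic_weights(_D([[0.6, 0.1], [0.2, 0.4]]))
        assert weights[0] == pytest.approx(60.0)
        assert weights[1] == pytest.approx(40.0)

    def test_five_post_three_topic_arithmetic_oracle(self):
        rows = np.array([
            [0.5, 0.1, 0.0],
            [0.2, 0.7, 0.1],
            [0.0, 0.0, 0.9],
            [0.3, 0.2, 0.1],
            [0.1, 0.4, 0.4],
        ])
        # dominant topics: 0, 1, 2, 0, 1 -> sums 0.8, 1.1, 0.9 (total 2.8)
        weights = topic_weights(_D(rows))
        assert weights[0] == pytest.approx(100 * 0.8 / 2.8)
        assert weights[1] == pytest.approx(100 * 1.1 / 2.8)
        assert weights[2] == pytest.approx(100 * 0.9 / 2.8)

    def test_weights_sum_to_hundred(self, fitted_pipeline):
        weights = topic_weights(fitted_pipeline["D"])
        assert sum(weights.values()) == pytest.approx(100.0, abs=0.1)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            topic_weights(DocumentEnsembleMatrix(
                D=np.empty((0, 2)), post_ids=(), windows=()
            ))


class TestSynonyms:
    def test_planted_pairs_rank_partner_first(self, fitted_pipeline):
        truth = fitted_pipeline["truth"]
        embedding = fitted_pipeline["embedding"]
        hits = trials = 0
        for a, b in truth.synonym_pairs:
            for query, partner in ((a, b), (b, a)):
                if query in embedding:
                    trials += 1
                    got = synonyms(query, embedding, topn=1)
                    hits += bool(got and got[0] == partner)
        assert trials > 0
        assert hits / trials >= 0.8

    def test_query_excluded(self, fitted_pipeline):
        embedding = fitted_pipeline["embedding"]
        term = embedding.terms[0]
        assert term not in synonyms(term, embedding, topn=5)


class TestAssembleDictionary:
    def _toy(self):
        """3 topics / 3 indicators with nested annotations: every
        social_capital post is a belonging post; learning separate."""
        D = _D([
            [0.9, 0.05, 0.05],   # topic 0
            [0.8, 0.1, 0.1],     # topic 0
            [0.1, 0.8, 0.1],     # topic 1
            [0.05, 0.05, 0.9],   # topic 2
        ])
        tmap = TopicIndicatorMap(
            indicators={
                0: frozenset({"belonging"}),
                1: frozenset({"belonging", "social_capital"}),
                2: frozenset({"learning"}),
            },
            labels={0: "Welcoming", 1: "Gratitude", 2: "Knowing"},
        )
        annotated = annotate(D, tmap)
        taxonomy = infer_taxonomy(collect_post_sets(annotated))
        vocab = Vocabulary(terms=("alpha", "beta", "gamma", "delta"))
        ensemble = EnsembleTopicModel(
            Wp=np.ones((2, 3)),
            Hp=np.array([
                [0.7, 0.1, 0.1, 0.1],
                [0.1, 0.7, 0.1, 0.1],
                [0.1, 0.1, 0.1, 0.7],
            ]),
            k_prime=3,
            row_origin=(("w", 0), ("w", 1)),
        )
        weights = topic_weights(D)
        from resdict.embedding import WordEmbedding

        embedding = WordEmbedding(
            terms=vocab.terms,
            vectors=np.random.default_rng(0).random((4, 3)),
        )
        return taxonomy, tmap, weights, ensemble, vocab, embedding

    def test_parents_match_toy_taxonomy(self):
        taxonomy, tmap, weights, ensemble, vocab, embedding = self._toy()
        d = assemble_dictionary(taxonomy, tmap, weights, ensemble, vocab,
                                embedding, n_words=2)
        assert d.entries["social_capital"]["parent"] == "belonging"
        assert d.entries["belonging"]["parent"] is None
        assert d.entries["learning"]["parent"] is None

    def test_indicator_without_topics_gets_empty_list(self):
        taxonomy, tmap, weights, ensemble, vocab, embedding = self._toy()
        d = assemble_dictionary(taxonomy, tmap, weights, ensemble, vocab,
                                embedding, n_words=2)
        assert d.entries["self_efficacy"]["topics"] == []

    def test_topics_consistent_with_mapping(self):
        taxonomy, tmap, weights, ensemble, vocab, embedding = self._toy()
        d = assemble_dictionary(taxonomy, tmap, weights, ensemble, vocab,
                                embedding, n_words=2)
        for indicator, entry in d.entries.items():
            for topic in entry["topics"]:
                assert indicator in tmap.for_topic(topic["topic_id"])
                assert topic["label"] == tmap.label(topic["topic_id"])
                for word, syns in topic["synonyms"].items():
                    assert word not in syns

    def test_unique_topic_weights_sum_to_hundred(self):
        taxonomy, tmap, weights, ensemble, vocab, embedding = self._toy()
        d = assemble_dictionary(taxonomy, tmap, weights, ensemble, vocab,
                                embedding, n_words=2)
        seen = {}
        for entry in d.entries.values():
            for topic in entry["topics"]:
                seen[topic["topic_id"]] = topic["weight_pct"]
        assert sum(seen.values()) == pytest.approx(100.0, abs=0.2)

    def test_bit_for_bit_reproducible(self, tmp_path):
        taxonomy, tmap, weights, ensemble, vocab, embedding = self._toy()
        paths = []
        for name in ("a.json", "b.json"):
            d = assemble_dictionary(taxonomy, tmap, weights, ensemble, vocab,
                                    embedding, n_words=2)
            d.to_json(tmp_path / name)
            paths.append(tmp_path / name)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_exports(self, tmp_path):
        taxonomy, tmap, weights, ensemble, vocab, embedding = self._toy()
        d = assemble_dictionary(taxonomy, tmap, weights, ensemble, vocab,
                                embedding, n_words=2)
        d.to_csv(tmp_path / "d.csv")
        d.to_markdown(tmp_path / "d.md")
        assert "Gratitude" in (tmp_path / "d.md").read_text()
        assert (tmp_path / "d.csv").read_text().count("\n") >= 4
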