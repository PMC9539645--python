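"""Shared fixtures: a hand-written natural-language corpus and a small
fitted synthetic pipeline reused across module tests."""

from __future__ import annotations

import pytest

from resdict.embedding import EmbeddingParams, train_embedding
from resdict.matrices import build_all_tfidf
from resdict.preprocessing import RawPost, preprocess_corpus
from resdict.synthetic import SyntheticConfig, generate_corpus
from resdict.topic_ensemble import (
    build_document_block,
    fit_base_layer,
    fit_ensemble,
    project_documents,
    stack_base_topics,
)

# Hand-written forum-style posts exercising the linguistic path
# (lemmatization, stop words, deidentification, quarter windows).
NATURAL_POSTS = [
    RawPost("n01", "2018-07-03", "The cats are sleeping on the warm couches today."),
    RawPost("n02", "2018-08-14", "Thanks @sam42 for sharing your stories with us.", "sam42"),
    RawPost("n03", "2018-09-30", "Walking daily helped my anxious thoughts settle down."),
    RawPost("n04", "2018-10-02", "Welcome to the community, feel free to introduce yourself."),
    RawPost("n05", "2018-11-11", "I tried journaling and it really improved my sleeping."),
    RawPost("n06", "2018-12-25", "Merry christmas everyone, wishing you peaceful holidays."),
    RawPost("n07", "2019-01-09", "My doctor suggested breathing exercises for panic attacks."),
    RawPost("n08", "2019-02-20", "Short one."),
    RawPost("n09", "2019-03-05", "Hugs to everyone struggling tonight, you are not alone."),
    RawPost("n10", "2019-04-18", "Learning new coping skills takes time and patience."),
    RawPost("n11", "2019-05-22", "The support here means so much, thank you friends."),
    RawPost("n12", "2019-06-30", "Celebrated my birthday quietly with family and cake."),
    RawPost("n13", "2019-07-07", "Running in the mornings keeps my mood steadier."),
    RawPost("n14", "2019-08-19", "Sharing experiences helps others feeling the same way."),
    RawPost("n15", "2019-09-23", "Slept badly again, the racing thoughts kept returning."),
    RawPost("n16", "2019-10-31", "Grateful for the kind words yesterday, they helped."),
    RawPost("n17", "2019-11-12", "Finding a good therapist changed everything for me."),
    RawPost("n18", "2019-12-01", "Happy new year wishes to all the lovely members here."),
    RawPost("n19", "2020-01-15", "Practicing mindfulness daily builds a calmer baseline."),
    RawPost("n20", "2020-02-28", "Reached out to a helpline and it went better than feared."),
]


@pytest.fixture(scope="session")
def natural_posts():
    return list(NATURAL_POSTS)


@pytest.fixture(scope="session")
def small_truth_corpus():
    """A small seeded ground-truth corpus (2 windows x 150 posts)."""
    config = SyntheticConfig(n_windows=2, docs_per_window=150, seed=11)
    posts, truth = generate_corpus(config)
    return config, posts, truth


@pytest.fixture(scope="session")
def fitted_pipeline():
    """A fully fitted small pipeline on a seeded synthetic corpus.

    Returns a dict with the corpus truth, tokenized posts, vocabulary,
    base models, stacked matrix, ensemble model, document matrices and a
    trained embedding.
    """
    config = SyntheticConfig(n_windows=3, docs_per_window=250, seed=29)
    posts, truth = generate_corpus(config)
    tokenized, report = preprocess_corpus(posts)
    matrices, vocab = build_all_tfidf(tokenized)
    models = fit_base_layer(matrices, k=config.n_topics, seed=3)
    stacked = stack_base_topics(models)
    ensemble = fit_ensemble(stacked, config.n_topics, seed=3)
    C = build_document_block(models)
    D = project_documents(C, ensemble)
    embedding = train_embedding(
        (p.terms for p in tokenized), EmbeddingParams(seed=3)
    )
    return {
        "config": config,
        "truth": truth,
        "tokenized": tokenized,
        "report": report,
        "vocab": vocab,
        "models": models,
        "stacked": stacked,
        "ensemble": ensemble,
        "C": C,
        "D": D,
        "embedding": embedding,
    }
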