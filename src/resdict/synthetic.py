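"""Forum-corpus simulator with known ground truth.

Generates quarter-windowed corpora of pseudo-word posts from planted
sparse topic-word distributions, with a nested indicator design that
mirrors the subsumption structure the taxonomy stage is meant to
recover: every post annotatable "social_capital" is also annotatable
"belonging", every "adaptive_capacity" post is also a "learning" post,
and "self_efficacy" posts are disjoint from both groups.

Pseudo-words (w0000, w0001, ...) pass through the linguistic
preprocessing unchanged, so the generator exercises the numeric pipeline
without depending on lemmatizer behaviour; a separate natural-language
fixture covers the linguistic path in tests.

Each document draws one true dominant topic; tokens come from that
topic's sparse support with probability ``topic_mixture`` and from a
background region otherwise. Planted synonym pairs live in the
background region and are always emitted adjacently, giving them
near-identical co-occurrence profiles. A configurable fraction of posts
is generated below the length filter to exercise short-post removal.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .annotation import (
    INDICATORS,
    AnnotatedPost,
    TopicIndicatorMap,
    annotate,
)
from .embedding import WordEmbedding
from .matrices import Vocabulary
from .preprocessing import RawPost
from .taxonomy import SubsumptionConfig, collect_post_sets, infer_taxonomy
from .topic_ensemble import DocumentEnsembleMatrix, EnsembleTopicModel, top_terms

_QUARTER_MONTHS = {1: (1, 3), 2: (4, 6), 3: (7, 9), 4: (10, 12)}

#: Default nested topic -> indicator design (six planted topics):
#: topics 0-1 realize belonging, topic 1 additionally social capital;
#: topics 2-3 realize learning, topic 3 additionally adaptive capacity;
#: topic 4 realizes self-efficacy alone; topic 5 maps to no indicator.
DEFAULT_INDICATOR_DESIGN: dict[int, frozenset[str]] = {
    0: frozenset({"belonging"}),
    1: frozenset({"belonging", "social_capital"}),
    2: frozenset({"learning"}),
    3: frozenset({"learning", "adaptive_capacity"}),
    4: frozenset({"self_efficacy"}),
    5: frozenset(),
}

#: Taxonomy implied by the nested design.
PLANTED_TAXONOMY: dict[str, str | None] = {
    "social_capital": "belonging",
    "belonging": None,
    "adaptive_capacity": "learning",
    "learning": None,
    "self_efficacy": None,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-shaped simulation parameters.

    Defaults emulate a quarterly forum corpus at desk scale: a handful of
    quarterly windows with a few hundred posts each, six well-separated
    planted topics present in every window, post lengths around 30 terms
    (matching the average retained post length of real peer-support
    corpora), and roughly 30% of posts too short to survive filtering.
    """

    n_windows: int = 4
    docs_per_window: int = 500
    vocab_size: int = 400
    n_topics: int = 6
    support_size: int = 12
    doc_len_mean: float = 30.0
    doc_len_min: int = 6
    topic_mixture: float = 0.85
    short_post_fraction: float = 0.3
    n_synonym_pairs: int = 10
    synonym_rate: float = 0.3
    min_terms: int = 5
    start_year: int = 2018
    start_quarter: int = 3
    seed: int = 0
    indicator_design: Mapping[int, frozenset[str]] | None = None

    def design(self) -> dict[int, frozenset[str]]:
        if self.indicator_design is not None:
            return {int(t): frozenset(v) for t, v in self.indicator_design.items()}
        return {
            t: DEFAULT_INDICATOR_DESIGN.get(t, frozenset())
            for t in range(self.n_topics)
        }


@dataclass
class GroundTruth:
    """Everything the generator knows about its corpus."""

    corpus_id: str
    posts: dict[str, dict]  # post_id -> {window, topic, indicators, short}
    prevalence: dict[tuple[str, str], float]  # (window, indicator) -> share
    taxonomy_parent: dict[str, str | None]
    synonym_pairs: list[tuple[str, str]]
    topic_supports: list[list[str]]  # support terms per topic, by planted weight
    indicator_map: dict[int, frozenset[str]]
    window_ids: list[str] = field(default_factory=list)

    def true_annotations(self, retained_only: bool = True) -> list[AnnotatedPost]:
        """Ground-truth annotations as AnnotatedPost records (bookkeeping)."""
        out = []
        for pid, rec in self.posts.items():
            if retained_only and rec["short"]:
                continue
            out.append(AnnotatedPost(
                post_id=pid,
                window_id=rec["window"],
                dominant_topic=rec["topic"],
                dominant_weight=1.0,
                indicators=frozenset(rec["indicators"]),
            ))
        return out


def _window_label(year: int, quarter: int) -> str:
    return f"{year}-Q{quarter}"


def _advance(year: int, quarter: int, steps: int) -> tuple[int, int]:
    q = quarter - 1 + steps
    return year + q // 4, q % 4 + 1


def generate_corpus(config: SyntheticConfig) -> tuple[list[RawPost], GroundTruth]:
    """Sample a corpus and record its ground truth.

    Topic supports are disjoint slices of the vocabulary with geometric
    within-support weights; the background region (everything outside all
    supports) hosts the planted synonym pairs. Fails if the vocabulary
    cannot host all supports plus the synonym pairs.
    """
    needed = config.n_topics * config.support_size + 2 * config.n_synonym_pairs
    if config.vocab_size < needed + 10:
        raise ValueError(
            f"vocab_size={config.vocab_size} too small for {config.n_topics} "
            f"topics x {config.support_size} support terms plus "
            f"{config.n_synonym_pairs} synonym pairs (need >= {needed + 10})"
        )
    rng = np.random.default_rng(config.seed)
    vocab = [f"w{i:04d}" for i in range(config.vocab_size)]

    supports: list[list[str]] = []
    probs: list[np.ndarray] = []
    for t in range(config.n_topics):
        lo = t * config.support_size
        supports.append(vocab[lo:lo + config.support_size])
        w = 0.7 ** np.arange(config.support_size)  # geometric rank profile
        probs.append(w / w.sum())

    pair_region_start = config.n_topics * config.support_size
    pairs = [
        (vocab[pair_region_start + 2 * i], vocab[pair_region_start + 2 * i + 1])
        for i in range(config.n_synonym_pairs)
    ]
    background = vocab[pair_region_start + 2 * config.n_synonym_pairs:]

    design = config.design()
    posts: list[RawPost] = []
    truth_posts: dict[str, dict] = {}
    window_ids: list[str] = []
    retained_counts: dict[str, int] = {}
    indicator_counts: dict[tuple[str, str], int] = {}

    pid = 0
    for w in range(config.n_windows):
        year, quarter = _advance(config.start_year, config.start_quarter, w)
        wid = _window_label(year, quarter)
        window_ids.append(wid)
        month_lo, month_hi = _QUARTER_MONTHS[quarter]
        topic_probs = rng.dirichlet(np.full(config.n_topics, 5.0))
        n_short = round(config.short_post_fraction * config.docs_per_window)
        short_flags = rng.permutation(config.docs_per_window) < n_short
        for short in short_flags:
            z = int(rng.choice(config.n_topics, p=topic_probs))
            short = bool(short)
            if short:
                length = int(rng.integers(1, config.min_terms))
            else:
                length = max(config.doc_len_min, int(rng.poisson(config.doc_len_mean)))
            from_topic = rng.random(length) < config.topic_mixture
            n_topic_tokens = int(from_topic.sum())
            topic_terms = iter(
                rng.choice(supports[z], size=n_topic_tokens, p=probs[z])
            )
            terms: list[str] = []
            for is_topic in from_topic:
                if is_topic:
                    terms.append(str(next(topic_terms)))
                elif pairs and not short and rng.random() < config.synonym_rate:
                    a, b = pairs[int(rng.integers(len(pairs)))]
                    terms.extend([a, b])
                else:
                    terms.append(str(rng.choice(background)))
            month = int(rng.integers(month_lo, month_hi + 1))
            day = int(rng.integers(1, 29))
            post_id = f"p{pid:06d}"
            pid += 1
            posts.append(RawPost(
                post_id=post_id,
                timestamp=f"{year:04d}-{month:02d}-{day:02d}",
                text=" ".join(terms),
                author_id=f"user{int(rng.integers(1000)):03d}",
            ))
            indicators = sorted(design.get(z, frozenset()))
            truth_posts[post_id] = {
                "window": wid, "topic": z, "indicators": indicators,
                "short": len(terms) < config.min_terms,
            }
            if len(terms) >= config.min_terms:
                retained_counts[wid] = retained_counts.get(wid, 0) + 1
                for name in indicators:
                    key = (wid, name)
                    indicator_counts[key] = indicator_counts.get(key, 0) + 1

    prevalence = {
        (wid, name): indicator_counts.get((wid, name), 0) / retained_counts[wid]
        for wid in window_ids
        for name in INDICATORS
        if retained_counts.get(wid)
    }
    corpus_id = "synthetic-" + hashlib.sha1(
        repr((config.seed, config.n_windows, config.docs_per_window,
              config.vocab_size, config.n_topics)).encode()
    ).hexdigest()[:12]
    truth = GroundTruth(
        corpus_id=corpus_id,
        posts=truth_posts,
        prevalence=prevalence,
        taxonomy_parent=dict(PLANTED_TAXONOMY),
        synonym_pairs=pairs,
        topic_supports=supports,
        indicator_map=design,
        window_ids=window_ids,
    )
    return posts, truth


@dataclass
class RecoveryReport:
    """How well the pipeline recovered the planted structure."""

    topic_matching: dict[int, int]  # planted topic -> fitted topic
    topic_overlaps: dict[int, float]
    mean_top_term_overlap: float
    prevalence_max_abs_error: float
    taxonomy_exact_match: bool
    synonym_top1_rate: float | None = None


def evaluate_recovery(
    ensemble: EnsembleTopicModel,
    D: DocumentEnsembleMatrix,
    vocab: Vocabulary,
    truth: GroundTruth,
    embedding: WordEmbedding | None = None,
    n_top: int = 10,
) -> RecoveryReport:
    """Compare fitted topics, prevalences, taxonomy and synonyms to truth.

    Fitted topics are matched to planted topics by maximum top-term
    overlap (optimal assignment); prevalence and taxonomy are then scored
    through the matched indicator mapping applied to the fitted D.
    """
    unknown = set(D.post_ids) - set(truth.posts)
    if unknown:
        raise ValueError(
            f"{len(unknown)} post ids not present in the ground truth "
            "(corpus mismatch)"
        )
    n_planted = len(truth.topic_supports)
    k_prime = ensemble.k_prime
    fitted_tops = [
        set(top_terms(ensemble, j, n_top, vocab)) for j in range(k_prime)
    ]
    planted_tops = [set(s[:n_top]) for s in truth.topic_supports]
    overlap = np.zeros((n_planted, k_prime))
    for i, pt in enumerate(planted_tops):
        for j, ft in enumerate(fitted_tops):
            overlap[i, j] = len(pt & ft) / max(len(pt), 1)
    rows, cols = linear_sum_assignment(-overlap)
    matching = {int(i): int(j) for i, j in zip(rows, cols)}
    overlaps = {int(i): float(overlap[i, matching[i]]) for i in matching}
    mean_overlap = float(np.mean(list(overlaps.values())))

    # indicator map for fitted topics via the matching
    fitted_map = TopicIndicatorMap(indicators={
        matching[i]: truth.indicator_map.get(i, frozenset())
        for i in matching
    })
    annotated = annotate(D, fitted_map)
    from .annotation import prevalence as prevalence_fn

    window_totals: dict[str, int] = {}
    for rec in truth.posts.values():
        if not rec["short"]:
            window_totals[rec["window"]] = window_totals.get(rec["window"], 0) + 1
    prev = prevalence_fn(annotated, window_totals)
    max_err = 0.0
    for _, row in prev.iterrows():
        true_share = truth.prevalence.get((row["window"], row["indicator"]), 0.0)
        max_err = max(max_err, abs(row["proportion"] - true_share))

    sets = collect_post_sets(annotated)
    inferred = infer_taxonomy(sets, SubsumptionConfig(mode="strict"))
    exact = all(
        inferred.parent.get(name) == truth.taxonomy_parent.get(name)
        for name in INDICATORS
    )

    syn_rate = None
    if embedding is not None and truth.synonym_pairs:
        hits = 0
        trials = 0
        for a, b in truth.synonym_pairs:
            for query, partner in ((a, b), (b, a)):
                if query in embedding:
                    trials += 1
                    best = embedding.most_similar(query, topn=1)
                    if best and best[0][0] == partner:
                        hits += 1
        syn_rate = hits / trials if trials else 0.0

    return RecoveryReport(
        topic_matching=matching,
        topic_overlaps=overlaps,
        mean_top_term_overlap=mean_overlap,
        prevalence_max_abs_error=float(max_err),
        taxonomy_exact_match=bool(exact),
        synonym_top1_rate=syn_rate,
    )


def planted_profile_matrix(
    n_profiles: int = 5,
    reps: int = 4,
    support_size: int = 40,
    noise: float = 0.05,
    seed: int = 0,
):
    """A stacked base-topic matrix with exactly ``n_profiles`` distinct rows.

    Each profile is a sparse geometric-weight distribution over its own
    disjoint term support, repeated ``reps`` times (one copy per pseudo
    window) with small additive noise — the ground truth for exercising
    coherence-driven selection of the ensemble topic count.
    """
    from .topic_ensemble import StackedTopicTermMatrix

    rng = np.random.default_rng(seed)
    m = n_profiles * support_size
    profiles = np.zeros((n_profiles, m))
    w = 0.8 ** np.arange(support_size)
    for i in range(n_profiles):
        profiles[i, i * support_size:(i + 1) * support_size] = w / w.sum()
    B = np.vstack([profiles] * reps)
    B = B + noise * 10 * B.mean() * rng.random(B.shape)
    origin = tuple((f"q{r}", i) for r in range(reps) for i in range(n_profiles))
    vocab = Vocabulary(terms=tuple(f"t{j:04d}" for j in range(m)))
    return StackedTopicTermMatrix(B=B, row_origin=origin), vocab


def cluster_embedding(
    vocab: Vocabulary,
    cluster_size: int,
    dim: int = 16,
    noise: float = 0.15,
    seed: int = 0,
) -> WordEmbedding:
    """Synthetic embedding whose terms fall into tight clusters.

    Consecutive blocks of ``cluster_size`` vocabulary terms share a basis
    direction plus Gaussian noise, so within-cluster cosine similarity is
    high and cross-cluster similarity is near zero.
    """
    rng = np.random.default_rng(seed)
    m = len(vocab)
    n_clusters = (m + cluster_size - 1) // cluster_size
    if n_clusters > dim:
        raise ValueError("dim must be at least the number of clusters")
    vectors = np.zeros((m, dim))
    for j in range(m):
        v = np.zeros(dim)
        v[j // cluster_size] = 1.0
        vectors[j] = v + noise * rng.standard_normal(dim)
    return WordEmbedding(terms=vocab.terms, vectors=vectors)


def write_corpus_csv(posts: Sequence[RawPost], path) -> None:
    """Emit the corpus in the CSV format the preprocessing module reads."""
    import csv
    from pathlib import Path

    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["post_id", "author_id", "timestamp", "text"]
        )
        writer.writeheader()
        for p in posts:
            writer.writerow({
                "post_id": p.post_id,
                "author_id": p.author_id or "",
                "timestamp": p.timestamp,
                "text": p.text,
            })


def write_ground_truth(truth: GroundTruth, path) -> None:
    import json
    from pathlib import Path

    payload = {
        "corpus_id": truth.corpus_id,
        "posts": truth.posts,
        "prevalence": [
            {"window": w, "indicator": n, "proportion": p}
            for (w, n), p in sorted(truth.prevalence.items())
        ],
        "taxonomy_parent": truth.taxonomy_parent,
        "synonym_pairs": [list(p) for p in truth.synonym_pairs],
        "topic_supports": truth.topic_supports,
        "indicator_map": {
            str(t): sorted(v) for t, v in truth.indicator_map.items()
        },
        "window_ids": truth.window_ids,
    }
    Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")
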