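"""End-to-end orchestration of the 4-phase dictionary pipeline.

Phase 1 preprocesses and windows the corpus; Phase 2 fits the two-layer
topic ensemble and selects k' by coherence; Phase 3 applies the human
topic -> indicator mapping and measures prevalence; Phase 4 infers the
subsumption taxonomy and assembles the dictionary. The human coding step
is an explicit break point: without a mapping file the run stops after
Phase 2 and emits a mapping template listing each topic's top terms and
top posts for the coders.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy.io import mmwrite

from . import __version__
from .annotation import TopicIndicatorMap, annotate, annotations_to_csv, prevalence
from .dictionary import assemble_dictionary, topic_weights
from .embedding import EmbeddingParams, train_embedding
from .matrices import build_all_tfidf
from .preprocessing import PreprocessConfig, preprocess_corpus, read_corpus, write_tokenized
from .taxonomy import SubsumptionConfig, collect_post_sets, coverage, coverage_to_csv, infer_taxonomy
from .topic_ensemble import (
    build_document_block,
    fit_base_layer,
    fit_ensemble,
    project_documents,
    select_k_prime,
    stack_base_topics,
    top_posts,
    top_terms,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline knobs; defaults follow the method's stated values:
    k=10 base topics per window, k' searched over 10..20 by coherence,
    top-15 terms and top-20 posts for the mapping step, top-10 terms for
    coherence scoring."""

    input_path: str = ""
    output_dir: str = "resdict-run"
    mapping_path: str | None = None
    min_terms: int = 5
    k: int = 10
    k_prime_min: int = 10
    k_prime_max: int = 20
    k_prime: int | None = None  # fixed k' skips coherence selection
    n_map: int = 15  # top terms shown to coders
    n_coherence: int = 10  # top terms scored for coherence
    m_posts: int = 20  # top posts shown to coders
    embedding_dim: int = 100
    embedding_window: int = 5
    embedding_min_count: int = 5
    subsumption_mode: str = "strict"
    subsumption_threshold: float = 1.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls(**raw)


def run(config: PipelineConfig) -> Path:
    """Run every phase the inputs allow; returns the artifact directory.

    Artifacts: preprocessing report, tokenized posts, model bundle
    (matrices as MTX + metadata), coherence report, mapping template or
    annotations/prevalence/taxonomy/dictionary, and a run manifest.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    # ---- Phase 1: preprocessing --------------------------------------
    posts = read_corpus(config.input_path)
    pp_config = PreprocessConfig(min_terms=config.min_terms)
    tokenized, report = preprocess_corpus(posts, pp_config)
    write_tokenized(tokenized, out / "tokenized.jsonl")
    (out / "preprocess_report.json").write_text(
        json.dumps(report.to_dict(), indent=2), encoding="utf-8"
    )
    if not tokenized:
        raise RuntimeError("phase 1: no posts survived preprocessing")

    # ---- Phase 2: two-layer topic ensemble ---------------------------
    matrices, vocab = build_all_tfidf(tokenized)
    vocab.save(out / "vocabulary.txt")
    models = fit_base_layer(matrices, k=config.k, seed=config.seed)
    for model in models:
        mmwrite(str(out / f"W_{model.window_id}.mtx"), np.asarray(model.W))
        mmwrite(str(out / f"H_{model.window_id}.mtx"), np.asarray(model.H))
    stacked = stack_base_topics(models)
    mmwrite(str(out / "B.mtx"), np.asarray(stacked.B))

    embedding = train_embedding(
        (p.terms for p in tokenized),
        EmbeddingParams(
            dim=config.embedding_dim,
            window=config.embedding_window,
            min_count=config.embedding_min_count,
            seed=config.seed,
        ),
    )
    embedding.save(out / "embedding.txt")

    if config.k_prime is not None:
        chosen = config.k_prime
        coherence_payload = {"scores": {}, "chosen": chosen, "fixed": True}
    else:
        k_range = range(config.k_prime_min, config.k_prime_max + 1)
        cohrep = select_k_prime(
            stacked, k_range, embedding, vocab,
            seed=config.seed, top_n=config.n_coherence,
        )
        chosen = cohrep.chosen
        coherence_payload = {
            "scores": {str(k): v for k, v in cohrep.scores.items()},
            "chosen": chosen,
            "failures": cohrep.failures,
        }
    (out / "coherence_report.json").write_text(
        json.dumps(coherence_payload, indent=2), encoding="utf-8"
    )
    ensemble = fit_ensemble(stacked, chosen, seed=config.seed)
    C = build_document_block(models)
    D = project_documents(C, ensemble)
    mmwrite(str(out / "Hp.mtx"), np.asarray(ensemble.Hp))
    mmwrite(str(out / "Wp.mtx"), np.asarray(ensemble.Wp))
    mmwrite(str(out / "D.mtx"), np.asarray(D.D))
    (out / "D_posts.json").write_text(
        json.dumps({"post_ids": list(D.post_ids), "windows": list(D.windows)}),
        encoding="utf-8",
    )

    _write_manifest(out, config, report, chosen)

    # ---- Human break point: mapping template ------------------------
    if config.mapping_path is None or not Path(config.mapping_path).exists():
        template = {
            "topics": [
                {
                    "topic": t,
                    "label": "",
                    "indicators": [],
                    "top_terms": top_terms(ensemble, t, config.n_map, vocab),
                    "top_posts": top_posts(D, t, config.m_posts),
                }
                for t in range(chosen)
            ]
        }
        (out / "mapping_template.yaml").write_text(
            yaml.safe_dump(template, sort_keys=False), encoding="utf-8"
        )
        logger.info(
            "no topic-indicator mapping supplied; wrote mapping template and "
            "stopped after phase 2"
        )
        return out

    # ---- Phase 3: annotation and prevalence --------------------------
    tmap = TopicIndicatorMap.from_file(config.mapping_path)
    annotated = annotate(D, tmap)
    annotations_to_csv(annotated, out / "annotations.csv")
    prev = prevalence(annotated)
    prev.to_csv(out / "prevalence.csv", index=False)

    # ---- Phase 4: taxonomy and dictionary ----------------------------
    sets = collect_post_sets(annotated)
    sub_config = SubsumptionConfig(
        mode=config.subsumption_mode, threshold=config.subsumption_threshold
    )
    taxonomy = infer_taxonomy(sets, sub_config)
    taxonomy.to_json(out / "taxonomy.json")
    taxonomy.to_dot(out / "taxonomy.dot")
    coverage_to_csv(coverage(sets), out / "coverage.csv")

    weights = topic_weights(D)
    dictionary = assemble_dictionary(
        taxonomy, tmap, weights, ensemble, vocab, embedding,
        metadata={
            "k": config.k,
            "k_prime": chosen,
            "seed": config.seed,
            "n_posts": len(D.post_ids),
        },
    )
    dictionary.to_json(out / "dictionary.json")
    dictionary.to_csv(out / "dictionary.csv")
    dictionary.to_markdown(out / "dictionary.md")
    return out


def _write_manifest(out: Path, config: PipelineConfig, report, chosen: int) -> None:
    manifest = {
        "config": asdict(config),
        "k_prime_chosen": chosen,
        "preprocess": report.to_dict(),
        "version": __version__,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
    )
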