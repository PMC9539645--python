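"""Phase 4b: assembling the resilience dictionary.

The dictionary lists, per resilience indicator: its parent in the
subsumption taxonomy, the topics mapped to it by human coding, each
topic's relative weight (the share of summed dominant-topic membership
mass it captures, as a percentage — weights over all topics sum to 100),
its top-10 descriptor terms, and the 5 nearest embedding neighbours of
every descriptor term ("similar terms").
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .annotation import INDICATORS, NO_TOPIC, TopicIndicatorMap, dominant_topic
from .embedding import WordEmbedding
from .matrices import Vocabulary
from .taxonomy import ResilienceTaxonomy
from .topic_ensemble import DocumentEnsembleMatrix, EnsembleTopicModel, top_terms

logger = logging.getLogger(__name__)


@dataclass
class TopicEntry:
    """One topic inside a dictionary entry."""

    topic_id: int
    label: str
    weight_pct: float
    top_words: list[str]
    synonyms: dict[str, list[str]]


@dataclass
class ResilienceDictionary:
    """indicator -> (taxonomy parent, mapped topic entries), plus metadata."""

    entries: dict[str, dict]
    metadata: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"entries": self.entries, "metadata": self.metadata},
                       indent=2, sort_keys=True),
            encoding="utf-8",
        )

    def to_csv(self, path: str | Path) -> None:
        rows = []
        for indicator, entry in self.entries.items():
            for topic in entry["topics"]:
                rows.append({
                    "indicator": indicator,
                    "parent": entry["parent"] or "",
                    "topic_id": topic["topic_id"],
                    "label": topic["label"],
                    "weight_pct": topic["weight_pct"],
                    "top_words": " ".join(topic["top_words"]),
                })
        pd.DataFrame(rows).to_csv(path, index=False)

    def to_markdown(self, path: str | Path) -> None:
        lines = ["| Indicator | Parent | Topic | Weight (%) | Topic words |",
                 "|---|---|---|---|---|"]
        for indicator, entry in self.entries.items():
            for topic in entry["topics"]:
                lines.append(
                    f"| {indicator} | {entry['parent'] or ''} | {topic['label']} "
                    f"| {topic['weight_pct']} | {' '.join(topic['top_words'])} |"
                )
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def topic_weights(D: DocumentEnsembleMatrix) -> dict[int, float]:
    """Relative importance of each topic, in percent.

    Each post contributes its dominant-topic weight to that topic; sums
    are normalized across topics so all weights add to 100. Posts with an
    all-zero membership row contribute nothing.
    """
    if D.D.size == 0:
        raise ValueError("empty document-ensemble matrix")
    k = D.D.shape[1]
    sums = np.zeros(k)
    for row in D.D:
        t = dominant_topic(row)
        if t != NO_TOPIC:
            sums[t] += row[t]
    total = sums.sum()
    if total == 0:
        raise ValueError("no post has a nonzero dominant weight")
    return {t: float(100.0 * sums[t] / total) for t in range(k)}


def synonyms(
    term: str, embedding: WordEmbedding, topn: int = 5
) -> list[str]:
    """The topn most similar terms to ``term``, never including ``term``."""
    return [w for w, _ in embedding.most_similar(term, topn=topn)]


def assemble_dictionary(
    taxonomy: ResilienceTaxonomy,
    tmap: TopicIndicatorMap,
    weights: Mapping[int, float],
    ensemble: EnsembleTopicModel,
    vocab: Vocabulary,
    embedding: WordEmbedding,
    n_words: int = 10,
    n_synonyms: int = 5,
    metadata: Mapping | None = None,
) -> ResilienceDictionary:
    """Aggregate taxonomy, mapping, weights, topics and synonyms.

    One entry per indicator; indicators with no mapped topic get an empty
    topic list (logged). Weight percentages are rounded to one decimal.
    """
    entries: dict[str, dict] = {}
    for indicator in INDICATORS:
        topics = sorted(
            t for t, names in tmap.indicators.items() if indicator in names
        )
        if not topics:
            logger.info("indicator %s has no mapped topics", indicator)
        topic_entries = []
        for t in topics:
            words = top_terms(ensemble, t, n_words, vocab)
            topic_entries.append({
                "topic_id": t,
                "label": tmap.label(t),
                "weight_pct": round(float(weights.get(t, 0.0)), 1),
                "top_words": words,
                "synonyms": {
                    w: synonyms(w, embedding, topn=n_synonyms) for w in words
                },
            })
        entries[indicator] = {
            "parent": taxonomy.parent.get(indicator),
            "topics": topic_entries,
        }
    return ResilienceDictionary(entries=entries, metadata=dict(metadata or {}))
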