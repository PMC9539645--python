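"""Phase 3: annotating posts with indicators and measuring prevalence.

The topic -> indicator mapping is the product of human qualitative
coding (researchers read each ensemble topic's top terms and top posts
and attribute it to one or more resilience indicators); it enters the
pipeline as a reviewed configuration file and is never inferred
automatically. Each post is annotated with its dominant ensemble topic
(the argmax of its row in the document-ensemble matrix D) and inherits
that topic's indicators. Prevalence is, per window, the share of
retained posts annotated with each indicator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .topic_ensemble import DocumentEnsembleMatrix

logger = logging.getLogger(__name__)

#: The five resilience indicators of the Berkes-Ross community-resilience
#: framework, as realized in peer-support forums.
INDICATORS = (
    "social_capital",
    "belonging",
    "learning",
    "adaptive_capacity",
    "self_efficacy",
)

INDICATOR_DEFINITIONS: dict[str, str] = {
    "social_capital": (
        "access to social networks and the support, trust and integration "
        "they foster"
    ),
    "belonging": (
        "belonging to people, groups and places; acceptance as part of a "
        "group and the identity formation that follows"
    ),
    "learning": "access to knowledge, information and skill development",
    "adaptive_capacity": (
        "use of resources that enable adaptation and positive behaviour change"
    ),
    "self_efficacy": (
        "ability to self-organize or work toward feeling in a controlled state"
    ),
}

#: Sentinel dominant-topic value for posts whose membership row is all zero.
NO_TOPIC = -1


@dataclass(frozen=True)
class TopicIndicatorMap:
    """Human coding output: each ensemble topic's indicators and label."""

    indicators: Mapping[int, frozenset[str]]
    labels: Mapping[int, str] | None = None

    def __post_init__(self) -> None:
        for topic, names in self.indicators.items():
            bad = set(names) - set(INDICATORS)
            if bad:
                raise ValueError(
                    f"topic {topic}: unknown indicator(s) {sorted(bad)}"
                )

    def for_topic(self, topic: int) -> frozenset[str]:
        return frozenset(self.indicators.get(topic, frozenset()))

    def label(self, topic: int) -> str:
        if self.labels and topic in self.labels:
            return self.labels[topic]
        return f"topic-{topic}"

    @classmethod
    def from_file(cls, path: str | Path) -> "TopicIndicatorMap":
        """Load from YAML/JSON: a list of {topic, label, indicators} entries."""
        path = Path(path)
        raw = yaml.safe_load(path.read_text(encoding="utf-8"))
        entries = raw["topics"] if isinstance(raw, dict) else raw
        indicators: dict[int, frozenset[str]] = {}
        labels: dict[int, str] = {}
        for entry in entries:
            topic = int(entry["topic"])
            indicators[topic] = frozenset(entry.get("indicators") or [])
            if entry.get("label"):
                labels[topic] = str(entry["label"])
        return cls(indicators=indicators, labels=labels)

    def to_file(self, path: str | Path) -> None:
        entries = [
            {
                "topic": topic,
                "label": self.label(topic),
                "indicators": sorted(names),
            }
            for topic, names in sorted(self.indicators.items())
        ]
        Path(path).write_text(
            yaml.safe_dump({"topics": entries}, sort_keys=False), encoding="utf-8"
        )


@dataclass(frozen=True)
class AnnotatedPost:
    """A post with its dominant ensemble topic and inherited indicators."""

    post_id: str
    window_id: str
    dominant_topic: int  # NO_TOPIC when the membership row is all zero
    dominant_weight: float
    indicators: frozenset[str]


def dominant_topic(d_row: np.ndarray) -> int:
    """Index of the maximal membership weight; ties go to the lowest index.

    An all-zero row returns the NO_TOPIC sentinel: the post belongs to no
    ensemble topic and is excluded from prevalence numerators.
    """
    row = np.asarray(d_row, dtype=float)
    if row.size == 0:
        raise ValueError("empty membership row")
    if not row.any():
        return NO_TOPIC
    best = int(np.argmax(row))
    if np.count_nonzero(row == row[best]) > 1:
        logger.debug("dominant-topic tie at weight %g; lowest index %d kept",
                     row[best], best)
    return best


def annotate(
    D: DocumentEnsembleMatrix, tmap: TopicIndicatorMap
) -> list[AnnotatedPost]:
    """Annotate every post with its dominant topic and that topic's indicators.

    Topics missing from the mapping yield empty indicator sets (logged);
    the result is a pure function of D and the mapping.
    """
    if D.D.shape[0] != len(D.post_ids):
        raise ValueError("membership matrix and post ids are misaligned")
    unmapped = {
        t for t in range(D.D.shape[1]) if t not in tmap.indicators
    }
    if unmapped:
        logger.info("topics without indicator mapping: %s", sorted(unmapped))
    out = []
    for i, pid in enumerate(D.post_ids):
        topic = dominant_topic(D.D[i])
        weight = float(D.D[i, topic]) if topic != NO_TOPIC else 0.0
        names = tmap.for_topic(topic) if topic != NO_TOPIC else frozenset()
        out.append(AnnotatedPost(
            post_id=pid,
            window_id=D.windows[i],
            dominant_topic=topic,
            dominant_weight=weight,
            indicators=names,
        ))
    return out


def prevalence(
    annotated: Sequence[AnnotatedPost],
    window_totals: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Per-window share of retained posts annotated with each indicator.

    The denominator is every retained post in the window (posts with
    unmapped or absent dominant topics included), so windows stay
    comparable; a post with several indicators counts once per indicator,
    hence per-window proportions may sum above 1.

    Returns a tidy frame (window, indicator, proportion) ready for
    streamgraph rendering.
    """
    if window_totals is None:
        window_totals = {}
        for post in annotated:
            window_totals[post.window_id] = window_totals.get(post.window_id, 0) + 1
    counts: dict[tuple[str, str], int] = {}
    for post in annotated:
        for name in post.indicators:
            counts[(post.window_id, name)] = counts.get((post.window_id, name), 0) + 1
    records = []
    for window in sorted(window_totals):
        total = window_totals[window]
        if total == 0:
            logger.warning("window %s has no retained posts; proportions set to 0",
                           window)
        for name in INDICATORS:
            share = counts.get((window, name), 0) / total if total else 0.0
            records.append({"window": window, "indicator": name,
                            "proportion": share})
    return pd.DataFrame.from_records(records)


def annotations_to_csv(annotated: Sequence[AnnotatedPost], path: str | Path) -> None:
    pd.DataFrame.from_records([
        {
            "post_id": a.post_id,
            "window": a.window_id,
            "topic": a.dominant_topic,
            "weight": a.dominant_weight,
            "indicators": ";".join(sorted(a.indicators)),
        }
        for a in annotated
    ]).to_csv(path, index=False)
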