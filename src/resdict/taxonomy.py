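"""Phase 4a: subsumption taxonomy over resilience indicators.

Indicator x subsumes indicator y when the posts annotated with y are
(approximately) contained in the posts annotated with x; x is then the
broader construct whose realization accompanies every realization of y.
The default mode demands exact set containment; a thresholded mode in
the spirit of Sanderson-Croft subsumption accepts containment fractions
above a configurable t for noisy real-world annotations.

Among several subsumers of a node, the most specific one (smallest post
set) becomes the parent, yielding the deepest valid hierarchy. Equal
post sets produce no edge (logged), preserving antisymmetry.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .annotation import INDICATORS, AnnotatedPost

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SubsumptionConfig:
    """mode "strict" requires exact subset containment; "thresholded"
    accepts containment fractions >= threshold (default 0.8)."""

    mode: str = "strict"
    threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("strict", "thresholded"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError("threshold must be in (0, 1]")

    @property
    def t(self) -> float:
        return 1.0 if self.mode == "strict" else self.threshold


@dataclass
class ResilienceTaxonomy:
    """Forest over indicators: each node has at most one parent."""

    nodes: tuple[str, ...]
    parent: dict[str, str | None]
    containment: dict[tuple[str, str], float] = field(default_factory=dict)

    @property
    def roots(self) -> tuple[str, ...]:
        return tuple(n for n in self.nodes if self.parent.get(n) is None)

    def ancestors(self, node: str) -> list[str]:
        chain = []
        cur = self.parent.get(node)
        while cur is not None:
            chain.append(cur)
            cur = self.parent.get(cur)
        return chain

    def to_json(self, path: str | Path) -> None:
        payload = {
            "nodes": list(self.nodes),
            "parent": {n: self.parent.get(n) for n in self.nodes},
            "containment": [
                {"child": c, "parent": p, "fraction": f}
                for (c, p), f in sorted(self.containment.items())
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")

    def to_dot(self, path: str | Path) -> None:
        lines = ["digraph taxonomy {"]
        for n in self.nodes:
            lines.append(f'  "{n}";')
        for child, par in self.parent.items():
            if par is not None:
                lines.append(f'  "{par}" -> "{child}";')
        lines.append("}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def collect_post_sets(
    annotated: Sequence[AnnotatedPost],
    indicators: Sequence[str] = INDICATORS,
) -> dict[str, set[str]]:
    """Inverse index: indicator name -> set of post ids annotated with it.

    Every requested indicator is present in the result, possibly empty.
    """
    sets: dict[str, set[str]] = {name: set() for name in indicators}
    for post in annotated:
        for name in post.indicators:
            sets.setdefault(name, set()).add(post.post_id)
    return sets


def _containment(child: set, parent: set) -> float:
    """Fraction of the child's posts also annotated with the parent."""
    if not child:
        return 0.0
    return len(child & parent) / len(child)


def infer_taxonomy(
    sets: Mapping[str, set],
    config: SubsumptionConfig | None = None,
) -> ResilienceTaxonomy:
    """Induce the subsumption forest from indicator post sets.

    x is a candidate ancestor of y iff containment(y in x) >= t and the
    reverse containment is strictly smaller (rules out equal sets and
    self-loops); the parent of y is its smallest candidate ancestor.
    """
    config = config or SubsumptionConfig()
    if not any(sets.values()):
        raise ValueError("all indicator post sets are empty")
    nodes = tuple(sets.keys())
    containment: dict[tuple[str, str], float] = {}
    parent: dict[str, str | None] = {}
    for y in nodes:
        candidates = []
        for x in nodes:
            if x == y:
                continue
            fwd = _containment(set(sets[y]), set(sets[x]))
            rev = _containment(set(sets[x]), set(sets[y]))
            containment[(y, x)] = fwd
            if sets[y] and fwd >= config.t and rev < fwd:
                candidates.append(x)
            elif sets[y] and sets[x] and set(sets[y]) == set(sets[x]):
                logger.info("indicators %s and %s have equal post sets; no edge",
                            y, x)
        if candidates:
            # most specific subsumer: smallest post set, name as tie-break
            best = min(candidates, key=lambda x: (len(sets[x]), x))
            if len([x for x in candidates if len(sets[x]) == len(sets[best])]) > 1:
                logger.info("parent tie for %s; chose %s by name", y, best)
            parent[y] = best
        else:
            parent[y] = None
    taxonomy = ResilienceTaxonomy(nodes=nodes, parent=parent,
                                  containment=containment)
    _check_acyclic(taxonomy, config)
    return taxonomy


def _check_acyclic(taxonomy: ResilienceTaxonomy, config: SubsumptionConfig) -> None:
    for node in taxonomy.nodes:
        seen = {node}
        cur = taxonomy.parent.get(node)
        while cur is not None:
            if cur in seen:
                raise ValueError(
                    f"cycle in taxonomy involving {node!r} and {cur!r} "
                    f"(mode={config.mode}, t={config.t})"
                )
            seen.add(cur)
            cur = taxonomy.parent.get(cur)


def coverage(sets: Mapping[str, set]) -> dict[str, float]:
    """Relative post-set size per indicator (treemap rectangle areas).

    |posts(indicator)| / |union of all annotated posts|; overlapping
    indicators may sum above 1.
    """
    union: set = set()
    for s in sets.values():
        union |= set(s)
    if not union:
        raise ValueError("no annotated posts; coverage undefined")
    return {name: len(set(s)) / len(union) for name, s in sets.items()}


def coverage_to_csv(cov: Mapping[str, float], path: str | Path) -> None:
    pd.DataFrame(
        [{"indicator": k, "coverage": v} for k, v in sorted(cov.items())]
    ).to_csv(path, index=False)
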