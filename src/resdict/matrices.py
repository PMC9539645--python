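"""Per-window document-term matrices over a shared global vocabulary.

Each calendar-quarter window gets its own nonnegative TF-IDF matrix
(documents x terms), but all windows share one lexicographically ordered
global vocabulary so that topic-term matrices from different windows can
later be stacked column-aligned.

Weighting is raw term frequency times the smoothed inverse document
frequency ln((1+n)/(1+df)) + 1, computed within the window, with L2 row
normalization — the scikit-learn TF-IDF convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import scipy.sparse as sp
from scipy.io import mmread, mmwrite
from sklearn.feature_extraction.text import TfidfVectorizer

from .preprocessing import TokenizedPost


@dataclass(frozen=True)
class Vocabulary:
    """Ordered global term list with a term -> column-index mapping."""

    terms: tuple[str, ...]

    @property
    def index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.terms)}

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term: str) -> bool:
        return term in self.index

    def save(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.terms) + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        terms = [t for t in Path(path).read_text(encoding="utf-8").splitlines() if t]
        return cls(terms=tuple(terms))


@dataclass
class DocTermMatrix:
    """Nonnegative TF-IDF matrix for one window: rows are posts, columns terms."""

    window_id: str
    post_ids: tuple[str, ...]
    matrix: sp.csr_matrix  # shape (len(post_ids), len(vocabulary))

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape


def group_by_window(posts: Sequence[TokenizedPost]) -> dict[str, list[TokenizedPost]]:
    """Partition tokenized posts into per-window collections, windows sorted."""
    windows: dict[str, list[TokenizedPost]] = {}
    for p in posts:
        windows.setdefault(p.window_id, []).append(p)
    return {w: windows[w] for w in sorted(windows)}


def build_vocabulary(posts: Sequence[TokenizedPost]) -> Vocabulary:
    """Union of all terms across all windows, lexicographically ordered."""
    terms = {t for p in posts for t in p.terms}
    if not terms:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    return Vocabulary(terms=tuple(sorted(terms)))


def build_tfidf(
    window_posts: Sequence[TokenizedPost],
    vocab: Vocabulary,
    window_id: str | None = None,
) -> DocTermMatrix:
    """TF-IDF matrix for one window's posts over the global vocabulary.

    IDF is computed from document frequencies within this window only, so
    each quarterly collection is weighted on its own terms; columns for
    terms unseen in the window are all-zero.
    """
    if not window_posts:
        raise ValueError(f"window {window_id!r} has no posts")
    if window_id is None:
        window_id = window_posts[0].window_id
    vectorizer = TfidfVectorizer(
        analyzer=lambda post: post.terms,
        vocabulary=vocab.index,
        norm="l2",
        smooth_idf=True,
        sublinear_tf=False,
    )
    matrix = sp.csr_matrix(vectorizer.fit_transform(window_posts))
    return DocTermMatrix(
        window_id=window_id,
        post_ids=tuple(p.post_id for p in window_posts),
        matrix=matrix,
    )


def build_all_tfidf(
    posts: Sequence[TokenizedPost], vocab: Vocabulary | None = None
) -> tuple[dict[str, DocTermMatrix], Vocabulary]:
    """Group posts by window and build one TF-IDF matrix per window."""
    if vocab is None:
        vocab = build_vocabulary(posts)
    windows = group_by_window(posts)
    return {
        w: build_tfidf(wposts, vocab, window_id=w) for w, wposts in windows.items()
    }, vocab


def save_matrix(dtm: DocTermMatrix, prefix: str | Path) -> None:
    """Persist as Matrix Market plus a JSON sidecar of row post ids."""
    prefix = Path(prefix)
    mmwrite(str(prefix.with_suffix(".mtx")), dtm.matrix)
    sidecar = {"window_id": dtm.window_id, "post_ids": list(dtm.post_ids)}
    prefix.with_suffix(".json").write_text(json.dumps(sidecar), encoding="utf-8")


def load_matrix(prefix: str | Path) -> DocTermMatrix:
    prefix = Path(prefix)
    sidecar = json.loads(prefix.with_suffix(".json").read_text(encoding="utf-8"))
    matrix = sp.csr_matrix(mmread(str(prefix.with_suffix(".mtx"))))
    return DocTermMatrix(
        window_id=sidecar["window_id"],
        post_ids=tuple(sidecar["post_ids"]),
        matrix=matrix,
    )
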