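"""Word embeddings trained from the retained corpus.

Embeddings serve two purposes downstream: scoring topic coherence during
model selection, and expanding each dictionary topic word with its
nearest neighbours ("similar terms"). Neighbours reflect distributional
similarity — terms used in the same contexts — so antonym-style pairs can
surface alongside true synonyms; no filtering is applied.

The model is a count-based embedding: co-occurrence counts inside a
symmetric context window are turned into a positive pointwise mutual
information (PPMI) matrix, which is factorized by truncated SVD; the
embedding of a term is its row of U * sqrt(S). This family of embeddings
is deterministic given a seed (the seed only fixes the SVD starting
vector) and needs no iterative training, which keeps repeated pipeline
runs bit-identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import svds


@dataclass(frozen=True)
class EmbeddingParams:
    """Training hyperparameters: vector size, context window, frequency floor."""

    dim: int = 100
    window: int = 5
    min_count: int = 5
    seed: int = 0


@dataclass
class WordEmbedding:
    """Dense vectors per term with cosine-similarity queries."""

    terms: tuple[str, ...]
    vectors: np.ndarray  # len(terms) x dim
    params: EmbeddingParams = field(default_factory=EmbeddingParams)

    def __post_init__(self) -> None:
        self._index = {t: i for i, t in enumerate(self.terms)}
        norms = np.linalg.norm(self.vectors, axis=1)
        norms[norms == 0] = 1.0
        self._unit = self.vectors / norms[:, None]

    def __contains__(self, term: str) -> bool:
        return term in self._index

    def __len__(self) -> int:
        return len(self.terms)

    def vector(self, term: str) -> np.ndarray:
        return self.vectors[self._index[term]]

    def similarity(self, a: str, b: str) -> float:
        return float(self._unit[self._index[a]] @ self._unit[self._index[b]])

    def most_similar(self, term: str, topn: int = 5) -> list[tuple[str, float]]:
        """Nearest terms by cosine similarity, excluding the query itself."""
        if term not in self._index:
            warnings.warn(f"term {term!r} not in embedding vocabulary")
            return []
        i = self._index[term]
        sims = self._unit @ self._unit[i]
        order = [j for j in np.argsort(-sims, kind="stable") if j != i]
        return [(self.terms[j], float(sims[j])) for j in order[:topn]]

    def save(self, path: str | Path) -> None:
        """Persist in the plain word-vector text format (word v1 v2 ...)."""
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write(f"{len(self.terms)} {self.vectors.shape[1]}\n")
            for term, vec in zip(self.terms, self.vectors):
                fh.write(term + " " + " ".join(f"{x:.8g}" for x in vec) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "WordEmbedding":
        with Path(path).open(encoding="utf-8") as fh:
            n, dim = map(int, fh.readline().split())
            terms, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                terms.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        return cls(terms=tuple(terms), vectors=np.array(rows))


def train_embedding(
    corpus: Iterable[Sequence[str]],
    params: EmbeddingParams | None = None,
) -> WordEmbedding:
    """Train a PPMI-SVD embedding on tokenized posts.

    Terms occurring fewer than ``min_count`` times are dropped. The PPMI
    matrix counts co-occurrences within a symmetric window of
    ``params.window`` tokens; embedding dimension is capped below the
    vocabulary size as truncated SVD requires.
    """
    params = params or EmbeddingParams()
    docs = [list(doc) for doc in corpus]
    counts: dict[str, int] = {}
    for doc in docs:
        for t in doc:
            counts[t] = counts.get(t, 0) + 1
    vocab = sorted(t for t, c in counts.items() if c >= params.min_count)
    if not vocab:
        raise ValueError(
            f"no term reaches min_count={params.min_count}; corpus too small"
        )
    index = {t: i for i, t in enumerate(vocab)}
    v = len(vocab)

    rows: list[int] = []
    cols: list[int] = []
    for doc in docs:
        ids = [index[t] for t in doc if t in index]
        for i, ci in enumerate(ids):
            lo = max(0, i - params.window)
            for j in range(lo, i):
                rows.append(ci)
                cols.append(ids[j])
                rows.append(ids[j])
                cols.append(ci)
    if not rows:
        raise ValueError("no co-occurrence pairs; documents too short")
    data = np.ones(len(rows))
    C = sp.coo_matrix((data, (rows, cols)), shape=(v, v)).tocsr()

    total = C.sum()
    row_sums = np.asarray(C.sum(axis=1)).ravel()
    C = C.tocoo()
    pmi = np.log((C.data * total) / (row_sums[C.row] * row_sums[C.col]))
    keep = pmi > 0
    ppmi = sp.coo_matrix(
        (pmi[keep], (C.row[keep], C.col[keep])), shape=(v, v)
    ).tocsr()

    dim = min(params.dim, v - 1)
    if dim < 1:
        raise ValueError("vocabulary too small for a nontrivial embedding")
    rng = np.random.default_rng(params.seed)
    v0 = rng.random(v)
    U, S, _ = svds(ppmi, k=dim, v0=v0)
    order = np.argsort(-S)
    U, S = U[:, order], S[order]
    vectors = U * np.sqrt(S)[None, :]
    # fix SVD sign ambiguity: largest-magnitude coordinate positive per axis
    for j in range(vectors.shape[1]):
        col = vectors[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            vectors[:, j] = -col
    return WordEmbedding(terms=tuple(vocab), vectors=vectors, params=params)
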