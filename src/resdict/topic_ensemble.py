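"""Two-layer ensemble NMF topic modelling.

Layer 1 factorizes each quarterly TF-IDF matrix A ~= W H into k base
topics. The base topic-term rows from every window are stacked into a
matrix B (Q*k rows, one per base topic, columns aligned on the global
vocabulary). Layer 2 factorizes B ~= W' H' into k' ensemble topics that
capture themes recurring across windows. Per-post ensemble memberships
come from projecting the block-structured document-base-topic matrix C
through W': D = C W' (one row per retained post, one column per ensemble
topic).

The NMF solver is multiplicative updates under the Frobenius objective
with nonnegative-double-SVD initialization (zeros filled with small
seeded random values), so fits are reproducible given a seed and the
reconstruction error is non-increasing across iterations.

The number of ensemble topics k' is chosen by topic coherence: the mean
pairwise cosine similarity of each topic's top terms in a word-embedding
space, averaged over topics; the candidate with the highest mean
coherence wins (ties to the smaller k').
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from .embedding import WordEmbedding
from .matrices import DocTermMatrix, Vocabulary

logger = logging.getLogger(__name__)

_EPS = 1e-10


# ---------------------------------------------------------------------------
# NMF solver
# ---------------------------------------------------------------------------

def _nndsvd_init(
    A: np.ndarray, k: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Nonnegative double SVD initialization; zeros filled with small noise.

    Boutsidis-Gallopoulos scheme: split each singular-vector pair into its
    positive and negative parts and keep the dominant one. Zero entries are
    replaced by small seeded random values (the "ar" variant) so that
    multiplicative updates can move every coordinate.
    """
    n, m = A.shape
    U, S, Vt = np.linalg.svd(A, full_matrices=False)
    W = np.zeros((n, k))
    H = np.zeros((k, m))
    W[:, 0] = np.sqrt(S[0]) * np.abs(U[:, 0])
    H[0, :] = np.sqrt(S[0]) * np.abs(Vt[0, :])
    for j in range(1, min(k, len(S))):
        u, v = U[:, j], Vt[j, :]
        up, un = np.maximum(u, 0), np.maximum(-u, 0)
        vp, vn = np.maximum(v, 0), np.maximum(-v, 0)
        norm_p, norm_n = np.linalg.norm(up) * np.linalg.norm(vp), np.linalg.norm(un) * np.linalg.norm(vn)
        if norm_p >= norm_n:
            sigma = S[j] * norm_p
            if norm_p > 0:
                W[:, j] = np.sqrt(sigma) * up / np.linalg.norm(up)
                H[j, :] = np.sqrt(sigma) * vp / np.linalg.norm(vp)
        else:
            sigma = S[j] * norm_n
            if norm_n > 0:
                W[:, j] = np.sqrt(sigma) * un / np.linalg.norm(un)
                H[j, :] = np.sqrt(sigma) * vn / np.linalg.norm(vn)
    scale = A.mean() if A.size else 1.0
    fill = scale / 100.0 if scale > 0 else 1e-4
    W[W <= 0] = fill * rng.random(np.count_nonzero(W <= 0))
    H[H <= 0] = fill * rng.random(np.count_nonzero(H <= 0))
    return W, H


def fit_nmf(
    A: np.ndarray | sp.spmatrix,
    k: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
    normalize: bool = True,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Factorize a nonnegative matrix A ~= W H with k components.

    Multiplicative updates under the Frobenius loss, NNDSVD-based seeded
    initialization, iteration cap ``max_iter`` and relative-improvement
    tolerance ``tol``. When ``normalize`` is set, each row of H is scaled
    to unit sum with the inverse scaling applied to the matching column
    of W, so topic-term weights are comparable across topics.

    Returns (W, H, error_trace) where error_trace holds the Frobenius
    reconstruction error at initialization and after each sweep.
    """
    A = np.asarray(A.toarray() if sp.issparse(A) else A, dtype=float)
    if not np.all(np.isfinite(A)):
        raise ValueError("matrix contains non-finite entries")
    if np.any(A < 0):
        raise ValueError("matrix must be nonnegative")
    n, m = A.shape
    if not 1 <= k <= min(n, m):
        raise ValueError(f"k={k} outside valid range 1..{min(n, m)}")

    rng = np.random.default_rng(seed)
    W, H = _nndsvd_init(A, k, rng)
    err = float(np.linalg.norm(A - W @ H))
    trace = [err]
    for _ in range(max_iter):
        H *= (W.T @ A) / (W.T @ W @ H + _EPS)
        W *= (A @ H.T) / (W @ (H @ H.T) + _EPS)
        new_err = float(np.linalg.norm(A - W @ H))
        trace.append(new_err)
        if trace[0] > 0 and (err - new_err) / trace[0] < tol:
            err = new_err
            break
        err = new_err
    if normalize:
        W, H = _normalize_rows(W, H)
    return W, H, trace


def _normalize_rows(W: np.ndarray, H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scale H rows to unit sum, compensating in W (W H is unchanged)."""
    sums = H.sum(axis=1)
    ok = sums > 0
    H = H.copy()
    W = W.copy()
    H[ok] /= sums[ok, None]
    W[:, ok] *= sums[ok][None, :]
    if not ok.all():
        logger.warning("%d topic rows had zero mass; left unnormalized", (~ok).sum())
    return W, H


# ---------------------------------------------------------------------------
# Layer 1: base topics per window
# ---------------------------------------------------------------------------

@dataclass
class BaseTopicModel:
    """First-layer NMF fit for one window: A ~= W H with k base topics."""

    window_id: str
    post_ids: tuple[str, ...]
    W: np.ndarray  # posts x k
    H: np.ndarray  # k x m, rows unit-sum
    k: int
    error_trace: list[float] = field(default_factory=list)


@dataclass
class StackedTopicTermMatrix:
    """All base topic-term rows stacked: one row per (window, base topic)."""

    B: np.ndarray  # (Q*k) x m
    row_origin: tuple[tuple[str, int], ...]  # (window_id, base-topic index)


@dataclass
class EnsembleTopicModel:
    """Second-layer NMF fit on B: B ~= W' H' with k' ensemble topics."""

    Wp: np.ndarray  # (Q*k) x k'
    Hp: np.ndarray  # k' x m, rows unit-sum
    k_prime: int
    row_origin: tuple[tuple[str, int], ...]
    error_trace: list[float] = field(default_factory=list)


@dataclass
class DocumentEnsembleMatrix:
    """Per-post membership over ensemble topics: one row per retained post."""

    D: np.ndarray  # n x k'
    post_ids: tuple[str, ...]
    windows: tuple[str, ...]  # window of each row


@dataclass
class CoherenceReport:
    """Mean topic coherence per candidate k' and the selected value."""

    scores: dict[int, float]
    chosen: int
    failures: dict[int, str] = field(default_factory=dict)


def fit_base_layer(
    matrices: Mapping[str, DocTermMatrix], k: int, seed: int = 0
) -> list[BaseTopicModel]:
    """Fit k base topics independently in every window, in window order."""
    if not matrices:
        raise ValueError("no windows to fit")
    models = []
    for i, (window_id, dtm) in enumerate(sorted(matrices.items())):
        try:
            W, H, trace = fit_nmf(dtm.matrix, k, seed=seed + i)
        except ValueError as exc:
            raise ValueError(f"window {window_id}: {exc}") from exc
        models.append(BaseTopicModel(
            window_id=window_id, post_ids=dtm.post_ids,
            W=W, H=H, k=k, error_trace=trace,
        ))
    return models


def stack_base_topics(models: Sequence[BaseTopicModel]) -> StackedTopicTermMatrix:
    """Stack every window's H rows into B, tagging each row with its origin."""
    m = models[0].H.shape[1]
    for model in models:
        if model.H.shape[1] != m:
            raise ValueError(
                f"window {model.window_id}: H has {model.H.shape[1]} columns, expected {m}"
            )
    B = np.vstack([model.H for model in models])
    origin = tuple(
        (model.window_id, j) for model in models for j in range(model.k)
    )
    return StackedTopicTermMatrix(B=B, row_origin=origin)


def fit_ensemble(
    B: StackedTopicTermMatrix | np.ndarray,
    k_prime: int,
    seed: int = 0,
) -> EnsembleTopicModel:
    """Fit k' ensemble topics on the stacked base-topic matrix."""
    if isinstance(B, StackedTopicTermMatrix):
        mat, origin = B.B, B.row_origin
    else:
        mat = np.asarray(B)
        origin = tuple(("?", i) for i in range(mat.shape[0]))
    Wp, Hp, trace = fit_nmf(mat, k_prime, seed=seed)
    return EnsembleTopicModel(
        Wp=Wp, Hp=Hp, k_prime=k_prime, row_origin=origin, error_trace=trace
    )


# ---------------------------------------------------------------------------
# Document projection
# ---------------------------------------------------------------------------

def build_document_block(models: Sequence[BaseTopicModel]) -> DocumentEnsembleMatrix:
    """Assemble the block-structured document-base-topic matrix C.

    A post appears in exactly one window, so its row carries that window's
    W entries in the k columns belonging to the window and zeros elsewhere.
    The returned object reuses DocumentEnsembleMatrix as a (matrix, post
    ids, windows) carrier; its columns are base topics, not ensemble topics.
    """
    n = sum(len(model.post_ids) for model in models)
    total_k = sum(model.k for model in models)
    C = np.zeros((n, total_k))
    post_ids: list[str] = []
    windows: list[str] = []
    seen: set[str] = set()
    row = 0
    col = 0
    for model in models:
        for pid in model.post_ids:
            if pid in seen:
                raise ValueError(f"post {pid!r} appears in more than one window")
            seen.add(pid)
        nw = len(model.post_ids)
        C[row:row + nw, col:col + model.k] = model.W
        post_ids.extend(model.post_ids)
        windows.extend([model.window_id] * nw)
        row += nw
        col += model.k
    return DocumentEnsembleMatrix(D=C, post_ids=tuple(post_ids), windows=tuple(windows))


def project_documents(
    C: DocumentEnsembleMatrix, ensemble: EnsembleTopicModel
) -> DocumentEnsembleMatrix:
    """Project per-window document-topic weights onto the ensemble topics.

    D = C W', giving every original post a nonnegative membership weight
    over each ensemble topic.
    """
    if C.D.shape[1] != ensemble.Wp.shape[0]:
        raise ValueError(
            f"C has {C.D.shape[1]} base-topic columns but W' has "
            f"{ensemble.Wp.shape[0]} rows"
        )
    return DocumentEnsembleMatrix(
        D=C.D @ ensemble.Wp, post_ids=C.post_ids, windows=C.windows
    )


# ---------------------------------------------------------------------------
# Topic inspection
# ---------------------------------------------------------------------------

def top_terms(
    ensemble: EnsembleTopicModel, topic: int, n: int, vocab: Vocabulary
) -> list[str]:
    """Top-n descriptor terms of an ensemble topic, by descending weight.

    Ties are broken lexicographically; n larger than the vocabulary is
    truncated.
    """
    row = ensemble.Hp[topic]
    order = sorted(range(len(row)), key=lambda j: (-row[j], vocab.terms[j]))
    return [vocab.terms[j] for j in order[: min(n, len(row))]]


def top_posts(D: DocumentEnsembleMatrix, topic: int, m: int) -> list[str]:
    """Top-m most relevant posts for an ensemble topic (ties by corpus order)."""
    col = D.D[:, topic]
    order = np.argsort(-col, kind="stable")
    return [D.post_ids[i] for i in order[: min(m, len(col))]]


# ---------------------------------------------------------------------------
# Coherence and model selection
# ---------------------------------------------------------------------------

def topic_coherence(terms: Sequence[str], embedding: WordEmbedding) -> float:
    """Mean pairwise cosine similarity of a topic's top terms.

    Terms missing from the embedding vocabulary are skipped (and logged);
    with fewer than two embeddable terms the score is 0 with a warning.
    """
    vecs = []
    for t in terms:
        if t in embedding:
            vecs.append(embedding.vector(t))
        else:
            logger.debug("coherence: term %r not in embedding vocabulary", t)
    if len(vecs) < 2:
        warnings.warn("fewer than 2 embeddable terms; coherence set to 0")
        return 0.0
    V = np.array(vecs)
    norms = np.linalg.norm(V, axis=1)
    V = V / norms[:, None]
    sims = V @ V.T
    iu = np.triu_indices(len(vecs), k=1)
    return float(sims[iu].mean())


def select_k_prime(
    B: StackedTopicTermMatrix | np.ndarray,
    k_range: Sequence[int],
    embedding: WordEmbedding,
    vocab: Vocabulary,
    seed: int = 0,
    top_n: int = 10,
) -> CoherenceReport:
    """Choose the number of ensemble topics by mean topic coherence.

    Fits one ensemble model per candidate k', scores the mean coherence of
    its topics' top-``top_n`` terms, and returns the full report with the
    maximizing candidate (smallest k' on ties). Candidates whose fit fails
    are recorded and skipped.
    """
    if not len(k_range):
        raise ValueError("empty candidate range")
    scores: dict[int, float] = {}
    failures: dict[int, str] = {}
    for k_prime in k_range:
        try:
            ensemble = fit_ensemble(B, k_prime, seed=seed)
            coh = [
                topic_coherence(top_terms(ensemble, t, top_n, vocab), embedding)
                for t in range(k_prime)
            ]
            scores[int(k_prime)] = float(np.mean(coh))
        except ValueError as exc:
            failures[int(k_prime)] = str(exc)
    if not scores:
        raise ValueError("every candidate k' failed to fit")
    chosen = min(scores, key=lambda kp: (-scores[kp], kp))
    return CoherenceReport(scores=scores, chosen=chosen, failures=failures)
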