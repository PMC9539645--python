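"""Phase 1: linguistic preprocessing of forum posts.

Raw posts are deidentified, sentence-split, tokenized, part-of-speech
filtered, stop-word filtered and lemmatized; posts left with too few
content terms are dropped, and every surviving post is assigned to a
calendar-quarter window.

The tagger and lemmatizer are lightweight rule-based components: the
tagger removes closed-class function words and classifies the remainder
of the open-class vocabulary by suffix, and the lemmatizer strips the
common English inflectional suffixes (plural -s/-es/-ies, -ing, -ed).
They are intentionally shallow — adequate for bag-of-words topic
modelling, not for syntactic analysis.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, replace
from datetime import datetime
from pathlib import Path
from typing import Iterable, Sequence

from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS

logger = logging.getLogger(__name__)

USER_PLACEHOLDER = "[USER]"

#: Default part-of-speech tags kept for topic modelling (content words).
CONTENT_POS = frozenset({"NOUN", "VERB", "ADJ", "ADV"})

#: Default English stop-word list (scikit-learn's curated list).
DEFAULT_STOPWORDS = frozenset(ENGLISH_STOP_WORDS)


class PreprocessingError(ValueError):
    """Raised for malformed posts (e.g. unparseable timestamps)."""

    def __init__(self, message: str, post_id: str | None = None):
        super().__init__(message)
        self.post_id = post_id


@dataclass(frozen=True)
class RawPost:
    """A forum post as ingested: identifier, optional author, timestamp, text."""

    post_id: str
    timestamp: str
    text: str
    author_id: str | None = None


@dataclass(frozen=True)
class TokenizedPost:
    """A post after preprocessing: ordered lowercase lemmas plus its quarter."""

    post_id: str
    window_id: str
    terms: tuple[str, ...]


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunable preprocessing parameters.

    min_terms: posts with fewer surviving terms are removed (default 5).
    stopwords: function/filler words dropped from every post.
    allowed_pos: part-of-speech tags retained (default: content words).
    """

    min_terms: int = 5
    stopwords: frozenset[str] = DEFAULT_STOPWORDS
    allowed_pos: frozenset[str] = CONTENT_POS

    def __post_init__(self) -> None:
        if self.min_terms < 1:
            raise ValueError("min_terms must be >= 1")


@dataclass
class PreprocessReport:
    """Bookkeeping for a preprocessing run."""

    n_input: int
    n_retained: int
    n_removed: int
    n_terms: int

    @property
    def retained_pct(self) -> float:
        """Percentage of input posts kept, rounded to 2 decimals."""
        return round(100.0 * self.n_retained / self.n_input, 2)

    @property
    def removed_pct(self) -> float:
        return round(100.0 * self.n_removed / self.n_input, 2)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "n_removed": self.n_removed,
            "n_terms": self.n_terms,
            "retained_pct": self.retained_pct,
            "removed_pct": self.removed_pct,
        }


# ---------------------------------------------------------------------------
# Deidentification
# ---------------------------------------------------------------------------

def deidentify(post: RawPost) -> RawPost:
    """Blank the author identifier and mask its mentions inside the text.

    Any occurrence of the author's identifier (optionally prefixed with
    "@") is replaced with a fixed placeholder; everything else is left
    untouched. Posts without an author identifier pass through unchanged.
    """
    if not post.author_id:
        return post
    pattern = re.compile(r"@?\b" + re.escape(post.author_id) + r"\b", re.IGNORECASE)
    return replace(post, author_id=None, text=pattern.sub(USER_PLACEHOLDER, post.text))


# ---------------------------------------------------------------------------
# Tokenization: sentence split, POS tagging, stop words, lemmatization
# ---------------------------------------------------------------------------

_SENTENCE_RE = re.compile(r"[.!?]+")
_TOKEN_RE = re.compile(r"[A-Za-z][A-Za-z0-9'_-]*")

# Closed-class function words by category; they receive non-content tags so
# the default POS filter drops them even when a custom stop-word list is used.
_CLOSED_CLASS: dict[str, frozenset[str]] = {
    "DET": frozenset("a an the this that these those some any no each every".split()),
    "PRON": frozenset(
        "i me my mine you your yours he him his she her hers it its we us our ours "
        "they them their theirs who whom whose which what myself yourself himself "
        "herself itself ourselves themselves".split()
    ),
    "ADP": frozenset(
        "of in on at by for with about against between into through during before "
        "after above below to from up down out off over under".split()
    ),
    "CONJ": frozenset("and or but nor so yet because although while if unless".split()),
    "AUX": frozenset(
        "is are was were be been being am do does did have has had will would "
        "shall should can could may might must".split()
    ),
}
_CLOSED_TAG = {w: tag for tag, words in _CLOSED_CLASS.items() for w in words}

_ADJ_SUFFIXES = ("ous", "ful", "ive", "able", "ible", "al", "ic", "less", "ish")


def pos_tag(token: str) -> str:
    """Heuristic part-of-speech tag for a lowercase token.

    Closed-class words get their function tag; the open-class remainder is
    classified by suffix (-ly adverbs, -ing/-ed verbs, common adjectival
    suffixes) and defaults to NOUN.
    """
    tag = _CLOSED_TAG.get(token)
    if tag is not None:
        return tag
    if token.endswith("ly") and len(token) > 3:
        return "ADV"
    if token.endswith(("ing", "ed")) and len(token) > 4:
        return "VERB"
    if token.endswith(_ADJ_SUFFIXES) and len(token) > 4:
        return "ADJ"
    return "NOUN"


_LEMMA_EXCEPTIONS = {
    "men": "man",
    "women": "woman",
    "children": "child",
    "people": "people",
    "feet": "foot",
    "teeth": "tooth",
    "mice": "mouse",
    "feelings": "feeling",
}

_VOWELS = set("aeiou")


def _dedouble(stem: str) -> str:
    """running -> runn -> run; hopped -> hopp -> hop."""
    if len(stem) >= 3 and stem[-1] == stem[-2] and stem[-1] not in _VOWELS:
        return stem[:-1]
    return stem


def lemmatize(token: str) -> str:
    """Rule-based English lemmatizer for inflectional suffixes.

    Handles regular plurals (cats -> cat, boxes -> box, studies -> study),
    progressive forms (sleeping -> sleep) and simple past forms
    (hopped -> hop, tried -> try). Tokens containing digits (e.g. synthetic
    pseudo-words) are returned unchanged.
    """
    if any(ch.isdigit() for ch in token):
        return token
    if token in _LEMMA_EXCEPTIONS:
        return _LEMMA_EXCEPTIONS[token]
    if token.endswith("ies") and len(token) > 4:
        return token[:-3] + "y"
    if token.endswith("es") and len(token) > 3:
        stem = token[:-2]
        if stem.endswith(("s", "x", "z", "ch", "sh")):
            return stem
    if token.endswith("s") and len(token) > 3 and not token.endswith(("ss", "us", "is")):
        return token[:-1]
    if token.endswith("ing") and len(token) > 5:
        return _dedouble(token[:-3])
    if token.endswith("ied") and len(token) > 4:
        return token[:-3] + "y"
    if token.endswith("ed") and len(token) > 4:
        return _dedouble(token[:-2])
    return token


def tokenize(post: RawPost, config: PreprocessConfig | None = None) -> TokenizedPost:
    """Turn a (deidentified) post into an ordered list of content lemmas.

    Sentences are split on terminal punctuation, tokens are lowercased,
    POS-filtered, stop-word-filtered and lemmatized; the original token
    order is preserved. Empty text yields an empty term sequence.
    """
    config = config or PreprocessConfig()
    terms: list[str] = []
    for sentence in _SENTENCE_RE.split(post.text):
        for raw in _TOKEN_RE.findall(sentence):
            token = raw.lower()
            if token in config.stopwords:
                continue
            if pos_tag(token) not in config.allowed_pos:
                continue
            lemma = lemmatize(token)
            if lemma and lemma not in config.stopwords:
                terms.append(lemma)
    return TokenizedPost(
        post_id=post.post_id,
        window_id=assign_window(post),
        terms=tuple(terms),
    )


def filter_short(
    posts: Sequence[TokenizedPost], min_terms: int = 5
) -> list[TokenizedPost]:
    """Keep exactly the posts with at least ``min_terms`` terms, in order."""
    return [p for p in posts if len(p.terms) >= min_terms]


# ---------------------------------------------------------------------------
# Window assignment
# ---------------------------------------------------------------------------

def assign_window(post: RawPost) -> str:
    """Map a post's timestamp to its calendar-quarter label, e.g. ``2018-Q3``."""
    ts = post.timestamp
    dt: datetime | None = None
    if isinstance(ts, datetime):
        dt = ts
    else:
        try:
            dt = datetime.fromisoformat(str(ts).strip().replace("Z", "+00:00"))
        except ValueError:
            dt = None
    if dt is None:
        raise PreprocessingError(
            f"unparseable timestamp {ts!r} for post {post.post_id}",
            post_id=post.post_id,
        )
    quarter = (dt.month - 1) // 3 + 1
    return f"{dt.year}-Q{quarter}"


# ---------------------------------------------------------------------------
# Corpus-level driver and I/O
# ---------------------------------------------------------------------------

def preprocess_corpus(
    posts: Iterable[RawPost], config: PreprocessConfig | None = None
) -> tuple[list[TokenizedPost], PreprocessReport]:
    """Run deidentification, tokenization and length filtering over a corpus."""
    config = config or PreprocessConfig()
    tokenized = [tokenize(deidentify(p), config) for p in posts]
    retained = filter_short(tokenized, config.min_terms)
    report = PreprocessReport(
        n_input=len(tokenized),
        n_retained=len(retained),
        n_removed=len(tokenized) - len(retained),
        n_terms=len({t for p in retained for t in p.terms}),
    )
    logger.info(
        "preprocessed %d posts: retained %d (%.2f%%), removed %d (%.2f%%), %d terms",
        report.n_input, report.n_retained, report.retained_pct,
        report.n_removed, report.removed_pct, report.n_terms,
    )
    return retained, report


def read_corpus(path: str | Path) -> list[RawPost]:
    """Read a corpus of raw posts from CSV or JSONL.

    Expected columns/keys: ``post_id``, ``timestamp``, ``text`` and
    optionally ``author_id``.
    """
    path = Path(path)
    posts: list[RawPost] = []
    if path.suffix.lower() == ".csv":
        with path.open(newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                posts.append(_post_from_record(row))
    else:
        with path.open(encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line:
                    posts.append(_post_from_record(json.loads(line)))
    seen: set[str] = set()
    for p in posts:
        if p.post_id in seen:
            raise PreprocessingError(f"duplicate post_id {p.post_id!r}", p.post_id)
        seen.add(p.post_id)
    return posts


def _post_from_record(rec: dict) -> RawPost:
    return RawPost(
        post_id=str(rec["post_id"]),
        timestamp=str(rec["timestamp"]),
        text=str(rec.get("text") or ""),
        author_id=(str(rec["author_id"]) if rec.get("author_id") else None),
    )


def write_tokenized(posts: Sequence[TokenizedPost], path: str | Path) -> None:
    """Write tokenized posts as JSONL records."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for p in posts:
            fh.write(json.dumps({
                "post_id": p.post_id,
                "window_id": p.window_id,
                "terms": list(p.terms),
            }) + "\n")


def read_tokenized(path: str | Path) -> list[TokenizedPost]:
    posts = []
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                rec = json.loads(line)
                posts.append(TokenizedPost(
                    post_id=str(rec["post_id"]),
                    window_id=str(rec["window_id"]),
                    terms=tuple(rec["terms"]),
                ))
    return posts
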