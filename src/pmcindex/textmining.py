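"""Term frequencies, high-frequency keywords, and co-occurrence networks.

A generic, fully documented replacement for the content-mining preprocessing
stage of the original workflow: tokenize policy texts with a pluggable
segmenter, count terms, extract the top keywords, and build a weighted
undirected co-occurrence graph whose edge weight is the number of
co-occurrence units (documents, or sliding windows) containing both terms.

Term normalization is Unicode NFC plus lowercasing of cased scripts; no
stemming.  The default segmenter splits on whitespace after stripping
punctuation, which is deterministic and language-agnostic; a character
segmenter is provided for unsegmented CJK text, and any callable
``text -> list[str]`` can be passed directly.
"""

from __future__ import annotations

import re
import unicodedata
from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Callable, Iterable, Sequence

import networkx as nx

__all__ = [
    "TextMiningError",
    "Corpus",
    "TermStats",
    "SEGMENTERS",
    "get_segmenter",
    "tokenize",
    "top_terms",
    "cooccurrence",
]


class TextMiningError(ValueError):
    pass


# -- segmenters -----------------------------------------------------------

_PUNCT_EDGE = re.compile(r"^\W+|\W+$", re.UNICODE)


def _normalize(term: str) -> str:
    return unicodedata.normalize("NFC", term).lower()


def _whitespace_segmenter(text: str) -> list[str]:
    out = []
    for raw in text.split():
        tok = _PUNCT_EDGE.sub("", raw)
        if tok:
            out.append(tok)
    return out


def _character_segmenter(text: str) -> list[str]:
    """One token per non-space, non-punctuation character (for CJK text)."""
    return [ch for ch in text if not ch.isspace() and not unicodedata.category(ch).startswith("P")]


SEGMENTERS: dict[str, Callable[[str], list[str]]] = {
    "whitespace": _whitespace_segmenter,
    "character": _character_segmenter,
}


def get_segmenter(segmenter: str | Callable[[str], list[str]]) -> Callable[[str], list[str]]:
    if callable(segmenter):
        return segmenter
    try:
        return SEGMENTERS[segmenter]
    except KeyError:
        raise TextMiningError(
            f"unknown segmenter {segmenter!r}; available: {sorted(SEGMENTERS)}"
        ) from None


# -- corpus ---------------------------------------------------------------


@dataclass(frozen=True)
class Corpus:
    """A set of policy documents: ordered (policy id, UTF-8 text) pairs."""

    docs: tuple[tuple[str, str], ...]

    def __post_init__(self):
        pids = [pid for pid, _ in self.docs]
        if len(set(pids)) != len(pids):
            dupes = sorted({p for p in pids if pids.count(p) > 1})
            raise TextMiningError(f"duplicate document ids: {dupes}")
        for pid, text in self.docs:
            if not text or not text.strip():
                raise TextMiningError(f"document {pid!r} is empty")

    def __len__(self) -> int:
        return len(self.docs)

    def __iter__(self):
        return iter(self.docs)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "Corpus":
        return cls(tuple((str(p), str(t)) for p, t in pairs))

    @classmethod
    def from_dir(cls, path: str | Path, pattern: str = "*.txt") -> "Corpus":
        """Load ``<pid>.txt`` files from a directory, sorted by file name."""
        path = Path(path)
        files = sorted(path.glob(pattern))
        if not files:
            raise TextMiningError(f"no {pattern} documents in {path}")
        return cls.from_pairs((f.stem, f.read_text(encoding="utf-8")) for f in files)

    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for pid, text in self.docs:
            (path / f"{pid}.txt").write_text(text, encoding="utf-8")


@dataclass(frozen=True)
class TermStats:
    """Aggregate counts for one term across a corpus."""

    term: str
    count: int
    doc_freq: int


# -- operations -----------------------------------------------------------


def tokenize(
    text: str,
    segmenter: str | Callable[[str], list[str]] = "whitespace",
    stopwords: Iterable[str] = (),
    min_len: int = 1,
) -> list[str]:
    """Split a text into normalized terms.

    Stopword matching happens after normalization; ``min_len`` drops short
    tokens (set to 2 to remove single-character noise).
    """
    if not text:
        raise TextMiningError("cannot tokenize empty text")
    seg = get_segmenter(segmenter)
    stop = {_normalize(w) for w in stopwords}
    out = []
    for tok in seg(text):
        term = _normalize(tok)
        if len(term) < min_len or term in stop:
            continue
        out.append(term)
    return out


def _tokenized_docs(corpus: Corpus, **tok_kwargs) -> list[tuple[str, list[str]]]:
    return [(pid, tokenize(text, **tok_kwargs)) for pid, text in corpus]


def top_terms(corpus: Corpus, n: int, **tok_kwargs) -> list[TermStats]:
    """The ``n`` most frequent terms, by total count then lexicographically."""
    if n <= 0:
        raise TextMiningError("n must be positive")
    counts: Counter = Counter()
    doc_freq: Counter = Counter()
    for _, toks in _tokenized_docs(corpus, **tok_kwargs):
        counts.update(toks)
        doc_freq.update(set(toks))
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [TermStats(term=t, count=c, doc_freq=doc_freq[t]) for t, c in ranked[:n]]


def cooccurrence(
    corpus: Corpus,
    window: int | str = "document",
    vocabulary: Iterable[str] | None = None,
    **tok_kwargs,
) -> nx.Graph:
    """Weighted undirected term co-occurrence graph.

    ``window="document"`` counts, for each unordered term pair, the number
    of documents containing both (the coarse unit behind the published
    network diagram).  An integer ``window`` instead counts sliding windows
    of that many consecutive tokens; a pair is counted at most once per
    window position.  ``vocabulary`` restricts nodes to the given terms.
    No self-loops; weight(a, b) == weight(b, a) by construction.
    """
    if window != "document" and (not isinstance(window, int) or window < 1):
        raise TextMiningError(f"window must be 'document' or a positive integer, got {window!r}")
    vocab = set(vocabulary) if vocabulary is not None else None
    g = nx.Graph()
    pair_counts: Counter = Counter()
    node_counts: Counter = Counter()
    for _, toks in _tokenized_docs(corpus, **tok_kwargs):
        if vocab is not None:
            toks = [t for t in toks if t in vocab]
        node_counts.update(set(toks))
        if window == "document":
            units: Iterable[Sequence[str]] = [toks]
        else:
            w = int(window)
            if len(toks) <= w:
                units = [toks]
            else:
                units = (toks[i : i + w] for i in range(len(toks) - w + 1))
        for unit in units:
            for a, b in combinations(sorted(set(unit)), 2):
                pair_counts[(a, b)] += 1
    g.add_nodes_from(node_counts)
    nx.set_node_attributes(g, dict(node_counts), "doc_freq")
    g.add_weighted_edges_from((a, b, w) for (a, b), w in pair_counts.items())
    return g
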