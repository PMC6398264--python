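"""Embedded full-text index over clinical notes.

Replaces a standalone search server with an in-process inverted index
that honours the same document schema (document and patient identifiers,
document type, timestamp) and the same Norwegian analysis chain:
tokenization, case folding, stopword removal and stemming.

Queries support boolean operators (AND/OR/NOT, adjacency = AND), quoted
phrases, trailing ``~N`` fuzzy terms (edit distance 1 or 2) and
metadata filters (patient, document type, date range).  Ranking is
BM25 relevance modulated by a multiplicative exponential freshness
decay with a configurable half-life, so that among equally relevant
documents newer ones rank first.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Sequence

from .errors import IngestionError, QueryParseError
from .nor_stem import stem

_TOKEN_RE = re.compile(r"[^\W_]+", re.UNICODE)

_STOPWORDS: set[str] | None = None


def _stopwords() -> set[str]:
    global _STOPWORDS
    if _STOPWORDS is None:
        from .vocabulary import packaged_path
        words = packaged_path("stopwords_no.txt").read_text("utf-8").splitlines()
        _STOPWORDS = {w.strip() for w in words
                      if w.strip() and not w.startswith("#")}
    return _STOPWORDS


def tokenize(text: str) -> list[tuple[str, int, int]]:
    """Split on non-letter/digit boundaries; yields (token, start, end)."""
    return [(m.group(0), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


def analyze(text: str) -> list[str]:
    """Normalize text to index terms: tokenize, lowercase, stop, stem."""
    stop = _stopwords()
    out = []
    for token, _s, _e in tokenize(text):
        token = token.lower()
        if token in stop:
            continue
        out.append(stem(token))
    return out


# ---------------------------------------------------------------- documents --
@dataclass
class DocumentRecord:
    """One clinical note plus extraction-populated fields."""

    doc_id: str
    patient_id: str
    doc_type: str
    timestamp: str  # ISO-8601
    text: str
    extracted: dict[str, list] = field(default_factory=dict)

    def parsed_timestamp(self) -> datetime:
        return datetime.fromisoformat(self.timestamp)

    def to_json(self) -> dict:
        return {
            "doc_id": self.doc_id, "patient_id": self.patient_id,
            "doc_type": self.doc_type, "timestamp": self.timestamp,
            "text": self.text, "extracted": self.extracted,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "DocumentRecord":
        return cls(**obj)


def read_corpus(path: str | Path) -> list[DocumentRecord]:
    """Read a JSONL corpus, one document per line."""
    docs = []
    for line in Path(path).read_text("utf-8").splitlines():
        if line.strip():
            docs.append(DocumentRecord.from_json(json.loads(line)))
    return docs


def write_corpus(docs: Iterable[DocumentRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(json.dumps(doc.to_json(), ensure_ascii=False) + "\n")


# -------------------------------------------------------------------- query --
@dataclass(frozen=True)
class TermNode:
    term: str          # analyzed (stemmed) form
    fuzzy: int = 0     # max edit distance, 0 = exact


@dataclass(frozen=True)
class PhraseNode:
    terms: tuple[str, ...]


@dataclass(frozen=True)
class NotNode:
    child: object


@dataclass(frozen=True)
class AndNode:
    children: tuple


@dataclass(frozen=True)
class OrNode:
    children: tuple


@dataclass
class TextQuery:
    """A parsed query: boolean expression plus metadata filters and paging."""

    root: object | None                 # None = filter-only query
    patient_id: str | None = None
    doc_type: str | None = None
    date_from: str | None = None        # inclusive ISO date bounds
    date_to: str | None = None
    page: int = 1
    page_size: int = 10


_QUERY_TOKEN_RE = re.compile(
    r'\s*(?:(?P<lpar>\()|(?P<rpar>\))|(?P<phrase>"[^"]*")'
    r'|(?P<word>[^\s()"~]+)(?:~(?P<dist>\d))?)')


class _Parser:
    """Recursive-descent parser: OR < AND (adjacency binds as AND) < NOT."""

    def __init__(self, text: str):
        self.text = text
        self.tokens: list[tuple[str, str, int]] = []
        pos = 0
        while pos < len(text):
            if text[pos].isspace():
                pos += 1
                continue
            m = _QUERY_TOKEN_RE.match(text, pos)
            if not m or m.end() == pos:
                raise QueryParseError(
                    f"cannot tokenize query at position {pos}", pos)
            if m.group("lpar"):
                self.tokens.append(("(", "(", pos))
            elif m.group("rpar"):
                self.tokens.append((")", ")", pos))
            elif m.group("phrase") is not None:
                self.tokens.append(("phrase", m.group("phrase")[1:-1], pos))
            else:
                word = m.group("word")
                dist = m.group("dist")
                if word.upper() in ("AND", "OR", "NOT"):
                    self.tokens.append((word.upper(), word, pos))
                elif dist:
                    if dist not in ("1", "2"):
                        raise QueryParseError(
                            f"fuzzy distance must be 1 or 2 at position {pos}",
                            pos)
                    self.tokens.append(("fuzzy", f"{word}~{dist}", pos))
                else:
                    self.tokens.append(("word", word, pos))
            pos = m.end()
        self.i = 0

    def peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self):
        tok = self.peek()
        self.i += 1
        return tok

    def parse(self):
        node = self.expr()
        if self.peek() is not None:
            raise QueryParseError(
                f"unexpected token at position {self.peek()[2]}",
                self.peek()[2])
        return node

    def expr(self):
        children = [self.and_expr()]
        while self.peek() and self.peek()[0] == "OR":
            self.next()
            children.append(self.and_expr())
        return children[0] if len(children) == 1 else OrNode(tuple(children))

    def and_expr(self):
        children = [self.unary()]
        while True:
            tok = self.peek()
            if tok is None or tok[0] in ("OR", ")"):
                break
            if tok[0] == "AND":
                self.next()
                tok = self.peek()
                if tok is None:
                    raise QueryParseError("dangling AND", None)
            children.append(self.unary())
        return children[0] if len(children) == 1 else AndNode(tuple(children))

    def unary(self):
        tok = self.peek()
        if tok is None:
            raise QueryParseError("unexpected end of query", None)
        if tok[0] == "NOT":
            self.next()
            return NotNode(self.unary())
        return self.atom()

    def atom(self):
        tok = self.next()
        kind, value, pos = tok
        if kind == "(":
            node = self.expr()
            closing = self.next()
            if closing is None or closing[0] != ")":
                raise QueryParseError(f"unbalanced parenthesis at {pos}", pos)
            return node
        if kind == "phrase":
            terms = tuple(analyze(value))
            return PhraseNode(terms)
        if kind == "fuzzy":
            word, dist = value.rsplit("~", 1)
            analyzed = analyze(word)
            term = analyzed[0] if analyzed else word.lower()
            return TermNode(term, int(dist))
        if kind == "word":
            analyzed = analyze(value)
            if not analyzed:   # pure stopword: matches nothing
                return TermNode("\x00stopword:" + value.lower())
            return TermNode(analyzed[0])
        raise QueryParseError(f"unexpected token {value!r} at {pos}", pos)


def parse_query(text: str, *, patient_id: str | None = None,
                doc_type: str | None = None, date_from: str | None = None,
                date_to: str | None = None, page: int = 1,
                page_size: int = 10) -> TextQuery:
    """Parse a query string; empty text gives a filter-only query."""
    root = _Parser(text).parse() if text.strip() else None
    return TextQuery(root, patient_id, doc_type, date_from, date_to,
                     page, page_size)


# -------------------------------------------------------------------- index --
def edit_distance(a: str, b: str, limit: int = 2) -> int:
    """Levenshtein distance, capped at limit+1 for early exit."""
    if abs(len(a) - len(b)) > limit:
        return limit + 1
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        best = i
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1,
                           prev[j - 1] + (ca != cb)))
            best = min(best, cur[-1])
        if best > limit:
            return limit + 1
        prev = cur
    return prev[-1]


@dataclass
class SearchResult:
    doc_id: str
    score: float
    snippet: str
    timestamp: str


@dataclass
class SearchPage:
    results: list[SearchResult]
    total: int
    page: int
    page_size: int


class Index:
    """Inverted index with positional postings and stored metadata."""

    def __init__(self, freshness_half_life_days: float = 365.0,
                 k1: float = 1.2, b: float = 0.75):
        self.docs: dict[str, DocumentRecord] = {}
        self.postings: dict[str, dict[str, list[int]]] = {}
        self.doc_len: dict[str, int] = {}
        self.half_life = freshness_half_life_days
        self.k1 = k1
        self.b = b
        self.version = 0

    def add_document(self, doc: DocumentRecord) -> None:
        if doc.doc_id in self.docs:
            raise IngestionError(f"duplicate doc_id {doc.doc_id!r}")
        doc.parsed_timestamp()  # validates
        terms = analyze(doc.text)
        self.docs[doc.doc_id] = doc
        self.doc_len[doc.doc_id] = len(terms)
        for pos, term in enumerate(terms):
            self.postings.setdefault(term, {}).setdefault(
                doc.doc_id, []).append(pos)
        self.version += 1

    def add_all(self, docs: Iterable[DocumentRecord]) -> None:
        for doc in docs:
            self.add_document(doc)

    def vocabulary(self) -> list[str]:
        return sorted(self.postings)

    # -- filtering ----------------------------------------------------
    def _universe(self, query: TextQuery) -> set[str]:
        out = set()
        for doc in self.docs.values():
            if query.patient_id is not None and doc.patient_id != query.patient_id:
                continue
            if query.doc_type is not None and doc.doc_type != query.doc_type:
                continue
            ts = doc.timestamp[:10]
            if query.date_from is not None and ts < query.date_from:
                continue
            if query.date_to is not None and ts > query.date_to:
                continue
            out.add(doc.doc_id)
        return out

    # -- boolean matching ---------------------------------------------
    def _fuzzy_expansions(self, node: TermNode) -> list[str]:
        if node.fuzzy == 0:
            return [node.term]
        return [t for t in self.postings
                if edit_distance(node.term, t, node.fuzzy) <= node.fuzzy]

    def _match(self, node, universe: set[str]) -> set[str]:
        if isinstance(node, TermNode):
            out: set[str] = set()
            for term in self._fuzzy_expansions(node):
                out |= set(self.postings.get(term, ()))
            return out & universe
        if isinstance(node, PhraseNode):
            if not node.terms:
                return set()
            out = set()
            candidates = set(self.postings.get(node.terms[0], ()))
            for term in node.terms[1:]:
                candidates &= set(self.postings.get(term, ()))
            for doc_id in candidates & universe:
                starts = set(self.postings[node.terms[0]][doc_id])
                for offset, term in enumerate(node.terms[1:], 1):
                    starts &= {p - offset for p in self.postings[term][doc_id]}
                    if not starts:
                        break
                if starts:
                    out.add(doc_id)
            return out
        if isinstance(node, NotNode):
            return universe - self._match(node.child, universe)
        if isinstance(node, AndNode):
            out = universe
            for child in node.children:
                out = out & self._match(child, universe)
            return out
        if isinstance(node, OrNode):
            out = set()
            for child in node.children:
                out |= self._match(child, universe)
            return out
        raise TypeError(f"unknown query node {node!r}")

    # -- scoring -------------------------------------------------------
    def _positive_terms(self, node, negated: bool = False) -> set[str]:
        """Terms usable for relevance scoring (not under a NOT)."""
        if node is None:
            return set()
        if isinstance(node, TermNode):
            return set() if negated else set(self._fuzzy_expansions(node))
        if isinstance(node, PhraseNode):
            return set() if negated else set(node.terms)
        if isinstance(node, NotNode):
            return self._positive_terms(node.child, not negated)
        if isinstance(node, (AndNode, OrNode)):
            out: set[str] = set()
            for child in node.children:
                out |= self._positive_terms(child, negated)
            return out
        return set()

    def _bm25(self, doc_id: str, terms: set[str]) -> float:
        n = len(self.docs)
        if n == 0 or not terms:
            return 0.0
        avgdl = sum(self.doc_len.values()) / n
        score = 0.0
        dl = self.doc_len[doc_id]
        for term in terms:
            plist = self.postings.get(term, {})
            tf = len(plist.get(doc_id, ()))
            if tf == 0:
                continue
            df = len(plist)
            idf = math.log(1.0 + (n - df + 0.5) / (df + 0.5))
            denom = tf + self.k1 * (1 - self.b + self.b * dl / max(avgdl, 1e-9))
            score += idf * tf * (self.k1 + 1) / denom
        return score

    def _freshness(self, doc: DocumentRecord, newest: datetime) -> float:
        age_days = (newest - doc.parsed_timestamp()).total_seconds() / 86400.0
        return 0.5 ** (max(age_days, 0.0) / self.half_life)

    # -- search --------------------------------------------------------
    def match_set(self, query: TextQuery) -> set[str]:
        """Exact boolean match set (pre-ranking), filters applied first."""
        universe = self._universe(query)
        if query.root is None:
            return universe
        return self._match(query.root, universe)

    def search(self, query: TextQuery) -> SearchPage:
        matched = self.match_set(query)
        positive = self._positive_terms(query.root)
        newest = max((d.parsed_timestamp() for d in self.docs.values()),
                     default=datetime.now())

        scored = []
        for doc_id in matched:
            doc = self.docs[doc_id]
            relevance = self._bm25(doc_id, positive)
            fresh = self._freshness(doc, newest)
            score = (relevance if relevance > 0 else 1.0) * fresh
            scored.append((score, doc.timestamp, doc_id))
        # score desc, ties by recency desc, then doc_id asc (stable sorts)
        scored.sort(key=lambda t: t[2])
        scored.sort(key=lambda t: t[1], reverse=True)
        scored.sort(key=lambda t: t[0], reverse=True)

        start = (query.page - 1) * query.page_size
        page_items = scored[start:start + query.page_size]
        results = [
            SearchResult(doc_id, score,
                         highlight(self.docs[doc_id], query), ts)
            for score, ts, doc_id in page_items
        ]
        return SearchPage(results, len(scored), query.page, query.page_size)

    # -- persistence ---------------------------------------------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        payload = {
            "half_life": self.half_life, "k1": self.k1, "b": self.b,
            "docs": [d.to_json() for d in self.docs.values()],
        }
        (directory / "index.json").write_text(
            json.dumps(payload, ensure_ascii=False, sort_keys=True),
            encoding="utf-8")

    @classmethod
    def load(cls, directory: str | Path) -> "Index":
        payload = json.loads(
            (Path(directory) / "index.json").read_text("utf-8"))
        idx = cls(payload["half_life"], payload["k1"], payload["b"])
        idx.add_all(DocumentRecord.from_json(d) for d in payload["docs"])
        return idx


def build_index(docs: Sequence[DocumentRecord],
                freshness_half_life_days: float = 365.0) -> Index:
    """Index a corpus; duplicate doc_ids raise :class:`IngestionError`."""
    idx = Index(freshness_half_life_days)
    idx.add_all(docs)
    return idx


# ---------------------------------------------------------------- highlight --
def _match_spans(doc: DocumentRecord, query: TextQuery) -> list[tuple[int, int]]:
    stop = _stopwords()
    idx_terms: set[str] = set()
    fuzzy: list[TermNode] = []

    def collect(node, negated=False):
        if node is None:
            return
        if isinstance(node, TermNode):
            if not negated:
                if node.fuzzy:
                    fuzzy.append(node)
                else:
                    idx_terms.add(node.term)
        elif isinstance(node, PhraseNode):
            if not negated:
                idx_terms.update(node.terms)
        elif isinstance(node, NotNode):
            collect(node.child, not negated)
        elif isinstance(node, (AndNode, OrNode)):
            for child in node.children:
                collect(child, negated)

    collect(query.root)
    spans = []
    for token, s, e in tokenize(doc.text):
        low = token.lower()
        if low in stop:
            continue
        stemmed = stem(low)
        hit = stemmed in idx_terms or any(
            edit_distance(f.term, stemmed, f.fuzzy) <= f.fuzzy for f in fuzzy)
        if hit:
            spans.append((s, e))
    return spans


def highlight(doc: DocumentRecord, query: TextQuery,
              window: int = 150, marker: str = "**") -> str:
    """Snippet around the first match with matched spans marked.

    Returns "" when nothing in the document matches the positive query
    terms (e.g. filter-only queries match without any term).
    """
    spans = _match_spans(doc, query)
    if not spans:
        return ""
    first = spans[0][0]
    start = max(0, first - window // 3)
    end = min(len(doc.text), start + window)
    in_window = [(s, e) for s, e in spans if s >= start and e <= end]
    out = []
    cursor = start
    for s, e in in_window:
        out.append(doc.text[cursor:s])
        out.append(marker + doc.text[s:e] + marker)
        cursor = e
    out.append(doc.text[cursor:end])
    prefix = "…" if start > 0 else ""
    suffix = "…" if end < len(doc.text) else ""
    return prefix + "".join(out) + suffix
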