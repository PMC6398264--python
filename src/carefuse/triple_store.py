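"""In-memory triple store with OWL 2 QL-style query-time inference.

Answers the four generic graph-query shapes the record-assembly layer
issues (list patients, types of an individual, predicate-object list,
subject-predicate list) plus conjunctive triple-pattern queries.

Inference is performed by query-time expansion of class and property
constants over the registry hierarchy closure rather than by saturating
the store: a type pattern ``(?x, rdf:type, C)`` matches instances of any
subclass of C, and a property pattern matches any subproperty.  This
keeps the store minimal and mirrors the semantics of query rewriting.

A minimal SPARQL SELECT text form (basic graph patterns only) is
accepted alongside the programmatic pattern API.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from . import ns
from .errors import QueryParseError, UnsupportedQueryError
from .mapping_engine import Literal, Triple, TripleSet
from .vocabulary import TermKind, TermRegistry

Term = str  # IRI or variable ("?name")
PatternTerm = "str | Literal"


def is_var(term: object) -> bool:
    return isinstance(term, str) and term.startswith("?")


@dataclass(frozen=True)
class TriplePattern:
    """A triple pattern; each position is an IRI, a literal, or a ?variable."""

    subject: str
    predicate: str
    object: str | Literal


@dataclass
class BindingSet:
    """Query solutions under set semantics with a stable column order."""

    variables: list[str]
    rows: list[tuple] = field(default_factory=list)

    def as_dicts(self) -> list[dict]:
        return [dict(zip(self.variables, row)) for row in self.rows]

    def __len__(self) -> int:
        return len(self.rows)

    def __eq__(self, other) -> bool:
        return (isinstance(other, BindingSet)
                and self.variables == other.variables
                and set(self.rows) == set(other.rows))


def _sort_key(value) -> tuple:
    if isinstance(value, Literal):
        return (1, value.lexical, value.datatype)
    return (0, value, "")


class TripleStore:
    """Indexed set of triples with mutation tracking for cache invalidation."""

    def __init__(self, triples: Iterable[Triple] = ()) -> None:
        self._triples: TripleSet = set()
        self._by_subject: dict[str, set[Triple]] = {}
        self._by_predicate: dict[str, set[Triple]] = {}
        self._by_object: dict[object, set[Triple]] = {}
        #: incremented on every mutation; consumers use it to invalidate caches
        self.version = 0
        self.add_all(triples)

    def __len__(self) -> int:
        return len(self._triples)

    def __iter__(self):
        return iter(self._triples)

    def add(self, triple: Triple) -> None:
        if triple in self._triples:
            return
        self._triples.add(triple)
        self._by_subject.setdefault(triple.subject, set()).add(triple)
        self._by_predicate.setdefault(triple.predicate, set()).add(triple)
        self._by_object.setdefault(triple.object, set()).add(triple)
        self.version += 1

    def add_all(self, triples: Iterable[Triple]) -> None:
        for t in triples:
            self.add(t)

    def triples(self) -> TripleSet:
        return set(self._triples)

    def match(self, s: str | None, p: str | None,
              o: "str | Literal | None") -> set[Triple]:
        """All triples matching the given constants (None = wildcard)."""
        candidates: set[Triple] | None = None
        for constant, index in ((s, self._by_subject),
                                (p, self._by_predicate),
                                (o, self._by_object)):
            if constant is None:
                continue
            found = index.get(constant, set())
            candidates = found if candidates is None else candidates & found
        if candidates is None:
            return set(self._triples)
        return set(candidates)


# ------------------------------------------------------- the four GUI shapes --
def list_patients(store: TripleStore, registry: TermRegistry) -> list[str]:
    """IRIs of all individuals typed with the patient class or a subclass."""
    patient_classes = registry.descendants(registry.roots["patient"])
    out = {t.subject for c in patient_classes
           for t in store.match(None, ns.RDF_TYPE, c)}
    return sorted(out)


def types_of(individual: str, store: TripleStore,
             registry: TermRegistry) -> set[str]:
    """Asserted types plus all superclasses via the registry closure."""
    asserted = {t.object for t in store.match(individual, ns.RDF_TYPE, None)
                if isinstance(t.object, str)}
    out: set[str] = set()
    for c in asserted:
        out |= registry.ancestors(c) if c in registry else {c}
    return out


def predicate_object_list(individual: str,
                          store: TripleStore) -> list[tuple[str, object]]:
    """All (predicate, object) pairs with the individual as subject."""
    pairs = {(t.predicate, t.object) for t in store.match(individual, None, None)}
    return sorted(pairs, key=lambda po: (po[0], _sort_key(po[1])))


def subject_predicate_list(individual: str,
                           store: TripleStore) -> list[tuple[str, str]]:
    """All (subject, predicate) pairs with the individual as object."""
    pairs = {(t.subject, t.predicate)
             for t in store.match(None, None, individual)}
    return sorted(pairs)


# ----------------------------------------------------------------- evaluate --
def _expand_constants(pattern: TriplePattern,
                      registry: TermRegistry) -> tuple[list[str], list[object]]:
    """Predicate and (for type patterns) object alternatives under inference."""
    if is_var(pattern.predicate):
        raise UnsupportedQueryError(
            "an unbound predicate variable cannot be combined with "
            "subclass/subproperty inference")
    preds: list[str] = [pattern.predicate]
    if (pattern.predicate in registry
            and registry[pattern.predicate].kind in (
                TermKind.OBJECT_PROPERTY, TermKind.DATATYPE_PROPERTY)):
        preds = sorted(registry.descendants(pattern.predicate))

    objs: list[object] = [pattern.object]
    if (pattern.predicate == ns.RDF_TYPE
            and isinstance(pattern.object, str)
            and not is_var(pattern.object)
            and pattern.object in registry
            and registry[pattern.object].kind is TermKind.CLASS):
        objs = sorted(registry.descendants(pattern.object))
    return preds, objs


def evaluate(patterns: Sequence[TriplePattern], store: TripleStore,
             registry: TermRegistry) -> BindingSet:
    """Join a basic graph pattern over the store with inference.

    Type patterns match instances of any subclass of the named class;
    property patterns match any subproperty.  Results are duplicate-free
    and deterministically ordered.
    """
    variables: list[str] = []
    for p in patterns:
        for term in (p.subject, p.predicate, p.object):
            if is_var(term) and term not in variables:
                variables.append(term)

    solutions: list[dict] = [{}]
    for pattern in patterns:
        preds, objs = _expand_constants(pattern, registry)
        next_solutions: list[dict] = []
        for binding in solutions:
            s = binding.get(pattern.subject) if is_var(pattern.subject) \
                else pattern.subject
            bound_obj = (binding.get(pattern.object)
                         if is_var(pattern.object) else None)
            for pred in preds:
                for obj_alt in objs:
                    if is_var(pattern.object):
                        o = bound_obj  # None = wildcard if still unbound
                    else:
                        o = obj_alt
                    for t in store.match(s, pred, o):
                        new = dict(binding)
                        consistent = True
                        for term, value in ((pattern.subject, t.subject),
                                            (pattern.object, t.object)):
                            if is_var(term):
                                if term in new and new[term] != value:
                                    consistent = False
                                    break
                                new[term] = value
                        if consistent:
                            next_solutions.append(new)
        solutions = next_solutions

    rows = {tuple(sol.get(v) for v in variables) for sol in solutions}
    out = BindingSet(variables, sorted(rows, key=lambda r: tuple(
        _sort_key(v) for v in r)))
    return out


# -------------------------------------------------------------- SPARQL-lite --
_PREFIX_RE = re.compile(r"PREFIX\s+(\w*):\s*<([^>]*)>", re.I)
_SELECT_RE = re.compile(
    r"SELECT\s+(?P<proj>[^{]+)\s*WHERE\s*\{(?P<body>.*)\}\s*$",
    re.I | re.S)


def _parse_term(token: str, prefixes: dict[str, str]) -> str | Literal:
    if token.startswith("?"):
        return token
    if token == "a":
        return ns.RDF_TYPE
    if token.startswith("<") and token.endswith(">"):
        return token[1:-1]
    if token.startswith('"'):
        m = re.match(r'^"(.*)"(?:\^\^<?([^<>]*)>?)?$', token)
        if not m:
            raise QueryParseError(f"bad literal token {token!r}")
        lexical, dt = m.group(1), m.group(2)
        key = "string"
        if dt:
            for k, v in ns.LITERAL_DATATYPES.items():
                if v == dt:
                    key = k
        return Literal(lexical, key)
    if ":" in token:
        prefix, local = token.split(":", 1)
        if prefix not in prefixes:
            raise QueryParseError(f"undeclared prefix {prefix!r}")
        return prefixes[prefix] + local
    raise QueryParseError(f"cannot parse term {token!r}")


def parse_sparql(text: str) -> tuple[list[str], list[TriplePattern]]:
    """Parse a minimal SPARQL SELECT (BGP only: no OPTIONAL/FILTER/etc.)."""
    prefixes = {m.group(1): m.group(2) for m in _PREFIX_RE.finditer(text)}
    body_text = _PREFIX_RE.sub("", text).strip()
    m = _SELECT_RE.search(body_text)
    if not m:
        raise QueryParseError("expected SELECT ... WHERE { ... }")
    proj = m.group("proj").split()
    if proj == ["*"]:
        projected: list[str] = []
    else:
        projected = proj
        for v in projected:
            if not v.startswith("?"):
                raise QueryParseError(f"projection must be variables, got {v!r}")
    patterns: list[TriplePattern] = []
    for stmt in m.group("body").split("."):
        stmt = stmt.strip()
        if not stmt:
            continue
        tokens = re.findall(r'"[^"]*"(?:\^\^\S+)?|\S+', stmt)
        if len(tokens) != 3:
            raise QueryParseError(f"expected 3 terms in pattern {stmt!r}")
        s, p, o = (_parse_term(t, prefixes) for t in tokens)
        if isinstance(s, Literal):
            raise QueryParseError("literal subjects are not allowed")
        patterns.append(TriplePattern(s, p, o))
    if not patterns:
        raise QueryParseError("empty graph pattern")
    return projected, patterns


def evaluate_sparql(text: str, store: TripleStore,
                    registry: TermRegistry) -> BindingSet:
    """Evaluate a minimal SPARQL SELECT string against the store."""
    projected, patterns = parse_sparql(text)
    result = evaluate(patterns, store, registry)
    if not projected:
        return result
    missing = [v for v in projected if v not in result.variables]
    if missing:
        raise QueryParseError(f"projected variables not in pattern: {missing}")
    idx = [result.variables.index(v) for v in projected]
    rows = {tuple(row[i] for i in idx) for row in result.rows}
    return BindingSet(projected, sorted(
        rows, key=lambda r: tuple(_sort_key(v) for v in r)))
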