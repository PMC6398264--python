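"""Independent brute-force oracles used to check the real implementations.

These deliberately avoid the package's store/index machinery: the graph
oracle saturates a plain list of triples with the full subclass and
subproperty closure and then joins patterns by naive backtracking; the
search oracle evaluates boolean queries document by document over the
analyzed token list.
"""

from __future__ import annotations

import random

from carefuse import ns
from carefuse.mapping_engine import Literal, Triple
from carefuse.text_index import (
    AndNode,
    DocumentRecord,
    NotNode,
    OrNode,
    PhraseNode,
    TermNode,
    TextQuery,
    analyze,
    edit_distance,
)
from carefuse.triple_store import TriplePattern, is_var
from carefuse.vocabulary import TermKind


# ------------------------------------------------------------- graph oracle --
def saturate(triples, registry):
    """Expand every triple with all superclass/superproperty consequences."""
    out = set()
    for t in triples:
        out.add((t.subject, t.predicate, t.object))
        if t.predicate == ns.RDF_TYPE and isinstance(t.object, str) \
                and t.object in registry:
            for sup in registry.ancestors(t.object):
                out.add((t.subject, ns.RDF_TYPE, sup))
        if t.predicate in registry and registry[t.predicate].kind in (
                TermKind.OBJECT_PROPERTY, TermKind.DATATYPE_PROPERTY):
            for sup in registry.ancestors(t.predicate):
                out.add((t.subject, sup, t.object))
    return out


def naive_evaluate(patterns, triples, registry):
    """All solutions of a BGP over the saturated graph, by backtracking.

    Returns a set of tuples ordered by first appearance of variables.
    """
    saturated = saturate(triples, registry)
    variables = []
    for p in patterns:
        for term in (p.subject, p.predicate, p.object):
            if is_var(term) and term not in variables:
                variables.append(term)

    solutions = set()

    def backtrack(i, binding):
        if i == len(patterns):
            solutions.add(tuple(binding.get(v) for v in variables))
            return
        p = patterns[i]
        for s, pred, o in saturated:
            trial = dict(binding)
            ok = True
            for term, value in ((p.subject, s), (p.predicate, pred),
                                (p.object, o)):
                if is_var(term):
                    if term in trial and trial[term] != value:
                        ok = False
                        break
                    trial[term] = value
                elif term != value:
                    ok = False
                    break
            if ok:
                backtrack(i + 1, trial)

    backtrack(0, {})
    return variables, solutions


def random_store_and_query(rng: random.Random, registry, n_triples=60,
                           n_patterns=2):
    """A random small graph plus a random 1-3 pattern query over it."""
    classes = [iri for iri, t in registry.terms.items()
               if t.kind is TermKind.CLASS]
    props = [iri for iri, t in registry.terms.items()
             if t.kind is TermKind.OBJECT_PROPERTY]
    individuals = [f"{ns.DATA}x/{i}" for i in range(15)]
    triples = set()
    for _ in range(n_triples):
        s = rng.choice(individuals)
        if rng.random() < 0.4:
            triples.add(Triple(s, ns.RDF_TYPE, rng.choice(classes)))
        elif rng.random() < 0.8:
            triples.add(Triple(s, rng.choice(props), rng.choice(individuals)))
        else:
            triples.add(Triple(s, ns.AHUS + "encounterTitle",
                               Literal(f"v{rng.randrange(5)}")))

    variables = ["?a", "?b", "?c"]
    patterns = []
    for k in range(n_patterns):
        subj = rng.choice(variables[:2]) if rng.random() < 0.8 \
            else rng.choice(individuals)
        if rng.random() < 0.5:
            obj = rng.choice(classes)
            patterns.append(TriplePattern(subj, ns.RDF_TYPE, obj))
        else:
            pred = rng.choice(props)
            obj = rng.choice(variables) if rng.random() < 0.7 \
                else rng.choice(individuals)
            patterns.append(TriplePattern(subj, pred, obj))
    return triples, patterns


# ------------------------------------------------------------ search oracle --
def doc_matches(doc: DocumentRecord, node) -> bool:
    """Evaluate a boolean query node against one document by scanning."""
    tokens = analyze(doc.text)

    def ev(n) -> bool:
        if isinstance(n, TermNode):
            if n.fuzzy:
                return any(edit_distance(n.term, t, n.fuzzy) <= n.fuzzy
                           for t in tokens)
            return n.term in tokens
        if isinstance(n, PhraseNode):
            k = len(n.terms)
            if k == 0:
                return False
            return any(tuple(tokens[i:i + k]) == n.terms
                       for i in range(len(tokens) - k + 1))
        if isinstance(n, NotNode):
            return not ev(n.child)
        if isinstance(n, AndNode):
            return all(ev(c) for c in n.children)
        if isinstance(n, OrNode):
            return any(ev(c) for c in n.children)
        raise TypeError(n)

    return ev(node)


def passes_filters(doc: DocumentRecord, q: TextQuery) -> bool:
    if q.patient_id is not None and doc.patient_id != q.patient_id:
        return False
    if q.doc_type is not None and doc.doc_type != q.doc_type:
        return False
    date = doc.timestamp[:10]
    if q.date_from is not None and date < q.date_from:
        return False
    if q.date_to is not None and date > q.date_to:
        return False
    return True


def scan_match_set(docs, q: TextQuery) -> set[str]:
    out = set()
    for doc in docs:
        if not passes_filters(doc, q):
            continue
        if q.root is None or doc_matches(doc, q.root):
            out.add(doc.doc_id)
    return out


_WORDS = ["blod", "puls", "pasient", "kontroll", "operasjon", "vondt",
          "smerte", "feber", "frisk", "medisin", "prøve", "svar"]


def random_corpus(rng: random.Random, n_docs=30):
    docs = []
    for i in range(n_docs):
        words = [rng.choice(_WORDS) for _ in range(rng.randrange(3, 15))]
        docs.append(DocumentRecord(
            doc_id=f"d{i}", patient_id=f"p{rng.randrange(3)}",
            doc_type=rng.choice(["andre", "epikrise"]),
            timestamp=f"201{rng.randrange(3, 7)}-0{rng.randrange(1, 9)}-1"
                      f"{rng.randrange(0, 9)}T12:00:00",
            text=" ".join(words)))
    return docs


def random_query_text(rng: random.Random) -> str:
    def term():
        w = rng.choice(_WORDS)
        r = rng.random()
        if r < 0.15:
            return f"{w}~1"
        if r < 0.25:
            return f'"{w} {rng.choice(_WORDS)}"'
        return w

    parts = [term()]
    for _ in range(rng.randrange(0, 3)):
        op = rng.choice(["AND", "OR", "AND NOT", ""])
        parts.append(f"{op} {term()}".strip())
    return " ".join(parts)
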