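"""The patient-care ontology: loading, validation and subclass reasoning.

The ontology integrates the two structured hospital sources.  It reuses
upper-level anchors from OBO Foundry ontologies (disease, health care
encounter, data item, scalar measurement datum) and a curated Disease
Ontology fragment carrying ICD-10 cross-references, and adds local terms
in a single artifact namespace for document types, encounter and
operation types, measurement subtypes (including the illness severity
score, ASA) and surgery-planning concepts.

Only the constructs this package relies on are modelled: class and
property hierarchies in the OWL 2 QL spirit.  No description-logic
reasoning is performed beyond transitive closure of ``subClassOf`` /
``subPropertyOf`` and acyclicity validation.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable

from rdflib import Graph, Literal as RdfLiteral, RDF, RDFS, OWL, URIRef
from rdflib.plugins.parsers.notation3 import BadSyntax

from . import ns
from .errors import (
    CodeSyntaxError,
    OntologyFormatError,
    OntologyValidationError,
    TermLookupError,
)

logger = logging.getLogger(__name__)

#: ICD-10 code syntax: a letter, two digits, optional dotted subdivision.
ICD10_RE = re.compile(r"^[A-Z][0-9]{2}(\.[0-9]{1,2})?$")


class TermKind(str, Enum):
    CLASS = "class"
    OBJECT_PROPERTY = "object_property"
    DATATYPE_PROPERTY = "datatype_property"
    ANNOTATION_PROPERTY = "annotation_property"


_KIND_BY_TYPE = {
    OWL.Class: TermKind.CLASS,
    OWL.ObjectProperty: TermKind.OBJECT_PROPERTY,
    OWL.DatatypeProperty: TermKind.DATATYPE_PROPERTY,
    OWL.AnnotationProperty: TermKind.ANNOTATION_PROPERTY,
}
_TYPE_BY_KIND = {v: k for k, v in _KIND_BY_TYPE.items()}


@dataclass
class OntologyTerm:
    """One ontology term (class or property).

    ``local`` is True when the term lives in the artifact namespace,
    False for terms imported from upstream ontologies.  ``xrefs`` holds
    external codes — ICD-10 codes for disease classes.
    """

    iri: str
    label: str
    kind: TermKind
    parents: list[str] = field(default_factory=list)
    local: bool = False
    xrefs: list[str] = field(default_factory=list)


class TermRegistry:
    """In-memory registry of ontology terms with hierarchy closure.

    ``roots`` maps anchor names (patient, disease, encounter, data_item,
    scalar_measurement) to their IRIs.
    """

    ROOTS = {
        "patient": ns.PATIENT_CLASS,
        "disease": ns.DISEASE_ROOT,
        "encounter": ns.ENCOUNTER_ROOT,
        "data_item": ns.DATA_ITEM_ROOT,
        "scalar_measurement": ns.SCALAR_MEASUREMENT_ROOT,
    }

    def __init__(self) -> None:
        self.terms: dict[str, OntologyTerm] = {}
        self.roots: dict[str, str] = dict(self.ROOTS)
        self._icd10: dict[str, str] = {}
        self._children: dict[str, list[str]] = {}

    # -- construction -------------------------------------------------
    def add(self, term: OntologyTerm) -> None:
        if term.iri in self.terms:
            raise OntologyValidationError(f"duplicate term IRI {term.iri}")
        self.terms[term.iri] = term

    def _rebuild(self) -> None:
        self._children = {}
        for t in self.terms.values():
            for p in t.parents:
                self._children.setdefault(p, []).append(t.iri)
        for v in self._children.values():
            v.sort()

    def validate(self) -> None:
        """Check all structural invariants; raise on the first violation."""
        for t in self.terms.values():
            for p in t.parents:
                parent = self.terms.get(p)
                if parent is None:
                    raise OntologyValidationError(
                        f"{t.iri} has unknown parent {p}")
                if parent.kind != t.kind:
                    raise OntologyValidationError(
                        f"{t.iri} ({t.kind.value}) has parent {p} of "
                        f"different kind ({parent.kind.value})")
            if t.local and not t.iri.startswith(ns.AHUS):
                raise OntologyValidationError(
                    f"local term {t.iri} outside the artifact namespace")
        cycle = self._find_cycle()
        if cycle:
            raise OntologyValidationError(
                "subclass hierarchy contains a cycle: {" + ", ".join(cycle) + "}")
        seen: dict[str, str] = {}
        for code, iri in self._icd10.items():
            if code in seen and seen[code] != iri:
                raise OntologyValidationError(
                    f"ICD-10 code {code} cross-references more than one class")
            seen[code] = iri
        self._rebuild()

    def _find_cycle(self) -> list[str] | None:
        WHITE, GREY, BLACK = 0, 1, 2
        color = {iri: WHITE for iri in self.terms}
        stack_trace: list[str] = []

        def visit(iri: str) -> list[str] | None:
            color[iri] = GREY
            stack_trace.append(iri)
            for p in self.terms[iri].parents:
                if p not in color:
                    continue
                if color[p] == GREY:
                    i = stack_trace.index(p)
                    return sorted(set(stack_trace[i:]))
                if color[p] == WHITE:
                    found = visit(p)
                    if found:
                        return found
            color[iri] = BLACK
            stack_trace.pop()
            return None

        for iri in sorted(self.terms):
            if color[iri] == WHITE:
                found = visit(iri)
                if found:
                    return found
        return None

    # -- lookups -------------------------------------------------------
    def __contains__(self, iri: str) -> bool:
        return iri in self.terms

    def __getitem__(self, iri: str) -> OntologyTerm:
        try:
            return self.terms[iri]
        except KeyError:
            raise TermLookupError(iri) from None

    def descendants(self, root: str) -> set[str]:
        """Reflexive-transitive closure downwards (root plus all descendants)."""
        if root not in self.terms:
            raise TermLookupError(root)
        out = {root}
        frontier = [root]
        while frontier:
            nxt = frontier.pop()
            for child in self._children.get(nxt, ()):
                if child not in out:
                    out.add(child)
                    frontier.append(child)
        return out

    def ancestors(self, iri: str) -> set[str]:
        """Reflexive-transitive closure upwards (term plus all ancestors)."""
        if iri not in self.terms:
            raise TermLookupError(iri)
        out = {iri}
        frontier = [iri]
        while frontier:
            nxt = frontier.pop()
            for p in self.terms[nxt].parents:
                if p in self.terms and p not in out:
                    out.add(p)
                    frontier.append(p)
        return out


def subclasses_of(root: str, registry: TermRegistry) -> set[str]:
    """Return ``root`` plus all transitive subclass descendants.

    The result is reflexive (a leaf class yields itself) and idempotent.
    """
    term = registry[root]
    if term.kind != TermKind.CLASS:
        raise TermLookupError(f"{root} is not a class")
    return registry.descendants(root)


def disease_for_icd10(code: str, registry: TermRegistry) -> str | None:
    """Resolve an ICD-10 code to its cross-referenced disease class.

    Returns None (and logs a warning) for syntactically valid but
    unmapped codes; raises :class:`CodeSyntaxError` for malformed codes.
    """
    if not ICD10_RE.match(code):
        raise CodeSyntaxError(f"not an ICD-10 code: {code!r}")
    iri = registry._icd10.get(code)
    if iri is None:
        logger.warning("ICD-10 code %s has no disease cross-reference", code)
    return iri


def count_local_terms(registry: TermRegistry, kind: TermKind | str) -> int:
    kind = TermKind(kind)
    return sum(1 for t in registry.terms.values() if t.local and t.kind == kind)


def _registry_from_graph(g: Graph, xrefs: dict[str, str] | None) -> TermRegistry:
    reg = TermRegistry()
    for rdf_type, kind in _KIND_BY_TYPE.items():
        for s in sorted(g.subjects(RDF.type, rdf_type)):
            if not isinstance(s, URIRef):
                continue
            iri = str(s)
            label = str(g.value(s, RDFS.label) or iri.rsplit("#", 1)[-1])
            pred = RDFS.subClassOf if kind is TermKind.CLASS else RDFS.subPropertyOf
            parents = sorted(str(p) for p in g.objects(s, pred)
                             if isinstance(p, URIRef))
            reg.add(OntologyTerm(
                iri=iri, label=label, kind=kind, parents=parents,
                local=iri.startswith(ns.AHUS)))
    if xrefs:
        for code, iri in xrefs.items():
            reg._icd10[code] = iri
            if iri in reg.terms:
                reg.terms[iri].xrefs.append(code)
    reg.validate()
    return reg


def load_icd10_xrefs(path: str | Path) -> dict[str, str]:
    """Read the two-column (code TAB class-IRI) cross-reference table."""
    out: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            code, iri = line.split("\t")
        except ValueError:
            raise OntologyFormatError(
                f"{path}:{lineno}: expected two tab-separated columns") from None
        if code in out and out[code] != iri:
            raise OntologyValidationError(
                f"ICD-10 code {code} cross-references more than one class")
        out[code] = iri
    return out


def load_ontology(path: str | Path,
                  xref_path: str | Path | None = None) -> TermRegistry:
    """Parse a Turtle ontology file into a validated registry.

    Parse failures raise :class:`OntologyFormatError` with line context;
    hierarchy cycles raise :class:`OntologyValidationError` naming the
    participating terms.
    """
    g = Graph()
    try:
        g.parse(str(path), format="turtle")
    except BadSyntax as exc:
        raise OntologyFormatError(
            f"{path}: Turtle parse error at line {exc.lines + 1}: "
            f"{exc._why}") from exc
    except FileNotFoundError:
        raise
    xrefs = load_icd10_xrefs(xref_path) if xref_path else None
    return _registry_from_graph(g, xrefs)


def serialize(registry: TermRegistry, path: str | Path) -> None:
    """Write the registry back out as Turtle (round-trip capable)."""
    g = Graph()
    g.bind("ahus", ns.AHUS)
    g.bind("obo", ns.OBO)
    g.bind("owl", OWL)
    for t in registry.terms.values():
        s = URIRef(t.iri)
        g.add((s, RDF.type, _TYPE_BY_KIND[t.kind]))
        g.add((s, RDFS.label, RdfLiteral(t.label)))
        pred = RDFS.subClassOf if t.kind is TermKind.CLASS else RDFS.subPropertyOf
        for p in t.parents:
            g.add((s, pred, URIRef(p)))
    Path(path).write_text(g.serialize(format="turtle"), encoding="utf-8")


def packaged_path(name: str) -> Path:
    """Path of a data file shipped inside the package."""
    return Path(str(resources.files("carefuse.data").joinpath(name)))


def load_packaged_ontology() -> TermRegistry:
    """Load the ontology and ICD-10 cross-references shipped with the package."""
    return load_ontology(packaged_path("ontology.ttl"),
                         packaged_path("icd10_xref.tsv"))
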