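"""Relational-to-RDF mapping: declarative rules, IRI minting, materialization.

Mappings follow the W3C R2RML vocabulary, restricted to the subset this
integration actually needs: logical tables (table name or embedded SQL
select), template-based subject maps with an optional class, column-based
predicate-object maps with XSD datatypes, and template-based referencing
object maps for foreign keys.  Unsupported R2RML constructs (graph maps,
inverse expressions, parent triples maps, constant-valued object maps)
are rejected by name at parse time.

Instead of rewriting queries against the live databases, the engine
materializes each source into an in-memory triple set.  Every triple
carries the identifier of the source system it came from, which the
record-fusion layer surfaces as provenance.
"""

from __future__ import annotations

import datetime as _dt
import logging
import re
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping
from urllib.parse import quote

from rdflib import Graph, RDF, URIRef
from rdflib.namespace import Namespace

from . import ns
from .errors import (
    MappingValidationError,
    MaterializationError,
    MintingError,
)
from .vocabulary import TermKind, TermRegistry

logger = logging.getLogger(__name__)

RR = Namespace("http://www.w3.org/ns/r2rml#")

_PLACEHOLDER_RE = re.compile(r"\{([^{}]+)\}")

_XSD_TO_KEY = {v: k for k, v in ns.LITERAL_DATATYPES.items()}


@dataclass(frozen=True)
class Literal:
    """A typed RDF literal with a canonical lexical form."""

    lexical: str
    datatype: str = "string"  # key into ns.LITERAL_DATATYPES

    def __post_init__(self):
        if self.datatype not in ns.LITERAL_DATATYPES:
            raise ValueError(f"unsupported literal datatype {self.datatype}")


@dataclass(frozen=True)
class Triple:
    """One subject–predicate–object statement tagged with its source system."""

    subject: str
    predicate: str
    object: str | Literal
    source: str = ""


TripleSet = set  # set[Triple]


@dataclass
class PredicateObjectMap:
    column: str
    predicate: str
    datatype: str = "string"


@dataclass
class RefObjectMap:
    column: str          # foreign-key column (first template placeholder)
    predicate: str       # object property IRI
    target_template: str


@dataclass
class MappingRule:
    """One triples map: a logical table plus its target triple shapes."""

    name: str
    logical_table: str           # table name, or "SELECT ..." when is_query
    subject_template: str
    subject_class: str | None = None
    predicate_object_maps: list[PredicateObjectMap] = field(default_factory=list)
    ref_object_maps: list[RefObjectMap] = field(default_factory=list)
    is_query: bool = False


# ------------------------------------------------------------------ minting --
def mint_iri(template: str, row: Mapping[str, object]) -> str:
    """Instantiate an IRI template from a row, percent-encoding values.

    Deterministic: the same row always yields the same IRI.  A null (or
    missing) placeholder value raises :class:`MintingError`.
    """
    def sub(match: re.Match) -> str:
        col = match.group(1)
        if col not in row.keys():
            raise MintingError(f"template column {col!r} missing from row")
        value = row[col]
        if value is None:
            raise MintingError(f"null value for template column {col!r}")
        return quote(str(value), safe="")

    return _PLACEHOLDER_RE.sub(sub, template)


# ------------------------------------------------------------------ parsing --
_UNSUPPORTED = [
    (RR.graphMap, "rr:graphMap"),
    (RR.inverseExpression, "rr:inverseExpression"),
    (RR.parentTriplesMap, "rr:parentTriplesMap"),
]


def parse_mappings(path: str | Path, registry: TermRegistry) -> list[MappingRule]:
    """Parse an R2RML Turtle file and validate every rule against the registry."""
    g = Graph()
    g.parse(str(path), format="turtle")

    for pred, name in _UNSUPPORTED:
        if next(g.subject_objects(pred), None) is not None:
            raise MappingValidationError(f"unsupported R2RML construct: {name}")

    rules: list[MappingRule] = []
    for tm in sorted(set(g.subjects(RR.logicalTable, None))):
        name = str(tm)
        lt = g.value(tm, RR.logicalTable)
        table = g.value(lt, RR.tableName)
        query = g.value(lt, RR.sqlQuery)
        if table is None and query is None:
            raise MappingValidationError(
                f"{name}: logical table needs rr:tableName or rr:sqlQuery")

        sm = g.value(tm, RR.subjectMap)
        template = g.value(sm, RR.template) if sm is not None else None
        if template is None:
            raise MappingValidationError(f"{name}: subject map needs rr:template")
        cls = g.value(sm, RR["class"])
        if cls is not None:
            c = str(cls)
            if c not in registry or registry[c].kind != TermKind.CLASS:
                raise MappingValidationError(
                    f"{name}: subject class {c} not a class in the registry")

        poms: list[PredicateObjectMap] = []
        roms: list[RefObjectMap] = []
        for pom in g.objects(tm, RR.predicateObjectMap):
            pred = g.value(pom, RR.predicate)
            om = g.value(pom, RR.objectMap)
            if pred is None or om is None:
                raise MappingValidationError(
                    f"{name}: predicate-object map needs rr:predicate and rr:objectMap")
            p = str(pred)
            if p not in registry:
                raise MappingValidationError(f"{name}: unknown property {p}")
            column = g.value(om, RR.column)
            obj_template = g.value(om, RR.template)
            if g.value(om, RR.constant) is not None:
                raise MappingValidationError(
                    f"{name}: unsupported R2RML construct: rr:constant object map")
            if column is not None:
                if registry[p].kind != TermKind.DATATYPE_PROPERTY:
                    raise MappingValidationError(
                        f"{name}: {p} used with a literal but is not a "
                        "datatype property")
                dt = g.value(om, RR.datatype)
                key = _XSD_TO_KEY.get(str(dt), "string") if dt else "string"
                poms.append(PredicateObjectMap(str(column), p, key))
            elif obj_template is not None:
                if registry[p].kind != TermKind.OBJECT_PROPERTY:
                    raise MappingValidationError(
                        f"{name}: {p} used with an IRI but is not an "
                        "object property")
                placeholders = _PLACEHOLDER_RE.findall(str(obj_template))
                if not placeholders:
                    raise MappingValidationError(
                        f"{name}: referencing object map template has no column")
                roms.append(RefObjectMap(placeholders[0], p, str(obj_template)))
            else:
                raise MappingValidationError(
                    f"{name}: object map needs rr:column or rr:template")

        poms.sort(key=lambda m: (m.predicate, m.column))
        roms.sort(key=lambda m: (m.predicate, m.column))
        rules.append(MappingRule(
            name=name,
            logical_table=str(query if table is None else table),
            subject_template=str(template),
            subject_class=str(cls) if cls is not None else None,
            predicate_object_maps=poms,
            ref_object_maps=roms,
            is_query=table is None,
        ))
    return rules


# ------------------------------------------------------------- literal forms --
_DATE_FORMATS = ["%Y-%m-%d", "%d.%m.%Y", "%d/%m/%Y"]
_DATETIME_FORMATS = [
    "%Y-%m-%dT%H:%M:%S", "%Y-%m-%d %H:%M:%S", "%Y-%m-%d %H:%M",
    "%d.%m.%Y %H:%M:%S", "%d.%m.%Y %H:%M",
]


def normalize_literal(value: object, datatype: str) -> Literal:
    """Canonicalize a column value; dates/times become ISO-8601."""
    if datatype == "date":
        if isinstance(value, _dt.date) and not isinstance(value, _dt.datetime):
            return Literal(value.isoformat(), "date")
        text = str(value).strip()
        for fmt in _DATE_FORMATS:
            try:
                return Literal(_dt.datetime.strptime(text, fmt).date().isoformat(),
                               "date")
            except ValueError:
                continue
        raise ValueError(f"unrecognized date format: {text!r}")
    if datatype == "dateTime":
        if isinstance(value, _dt.datetime):
            return Literal(value.isoformat(), "dateTime")
        text = str(value).strip()
        for fmt in _DATETIME_FORMATS:
            try:
                return Literal(_dt.datetime.strptime(text, fmt).isoformat(),
                               "dateTime")
            except ValueError:
                continue
        raise ValueError(f"unrecognized dateTime format: {text!r}")
    if datatype == "integer":
        return Literal(str(int(value)), "integer")
    if datatype == "decimal":
        d = float(value)
        lex = f"{d:g}" if d != int(d) else str(int(d))
        return Literal(lex, "decimal")
    return Literal(str(value), "string")


# -------------------------------------------------------------- materialize --
def _rows(conn: sqlite3.Connection, rule: MappingRule) -> list[sqlite3.Row]:
    conn.row_factory = sqlite3.Row
    sql = rule.logical_table if rule.is_query else f'SELECT * FROM "{rule.logical_table}"'
    try:
        return conn.execute(sql).fetchall()
    except sqlite3.OperationalError as exc:
        raise MaterializationError(
            f"rule {rule.name}: logical table {rule.logical_table!r}: {exc}"
        ) from exc


def materialize(rules: Iterable[MappingRule], conn: sqlite3.Connection,
                source: str = "") -> TripleSet:
    """Apply mapping rules to a relational source, producing a triple set.

    Per row: one rdf:type triple when the rule declares a class, one
    literal triple per mapped non-null column, one object triple per
    non-null foreign key.  Null columns produce no triple.  Rows whose
    subject cannot be minted (null key) are skipped with a warning.
    """
    out: TripleSet = set()
    for rule in rules:
        for row in _rows(conn, rule):
            keys = set(row.keys())
            try:
                subject = mint_iri(rule.subject_template, row)
            except MintingError as exc:
                logger.warning("rule %s: row skipped: %s", rule.name, exc)
                continue
            if rule.subject_class:
                out.add(Triple(subject, ns.RDF_TYPE, rule.subject_class, source))
            for pom in rule.predicate_object_maps:
                if pom.column not in keys:
                    raise MaterializationError(
                        f"rule {rule.name}: column {pom.column!r} missing from "
                        f"logical table {rule.logical_table!r}")
                value = row[pom.column]
                if value is None:
                    continue
                out.add(Triple(subject, pom.predicate,
                               normalize_literal(value, pom.datatype), source))
            for rom in rule.ref_object_maps:
                if rom.column not in keys:
                    raise MaterializationError(
                        f"rule {rule.name}: column {rom.column!r} missing from "
                        f"logical table {rule.logical_table!r}")
                if row[rom.column] is None:
                    continue
                out.add(Triple(subject, rom.predicate,
                               mint_iri(rom.target_template, row), source))
    return out


# ------------------------------------------------------------------- export --
def _nt_term(value: str | Literal) -> str:
    if isinstance(value, Literal):
        escaped = (value.lexical.replace("\\", "\\\\").replace('"', '\\"')
                   .replace("\n", "\\n").replace("\r", "\\r"))
        return f'"{escaped}"^^<{ns.LITERAL_DATATYPES[value.datatype]}>'
    return f"<{value}>"


def export_ntriples(triples: Iterable[Triple], path: str | Path) -> None:
    """Write triples as sorted N-Triples (deterministic for identical sets)."""
    lines = sorted(
        f"<{t.subject}> <{t.predicate}> {_nt_term(t.object)} ."
        for t in triples
    )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""),
                          encoding="utf-8")


def load_ntriples(path: str | Path, source: str = "") -> TripleSet:
    """Read an N-Triples file into a triple set (via rdflib)."""
    from rdflib import Literal as RdfLiteral

    g = Graph()
    g.parse(str(path), format="nt")
    out: TripleSet = set()
    for s, p, o in g:
        if isinstance(o, RdfLiteral):
            key = _XSD_TO_KEY.get(str(o.datatype), "string")
            obj: str | Literal = Literal(str(o), key)
        else:
            obj = str(o)
        out.add(Triple(str(s), str(p), obj, source))
    return out
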