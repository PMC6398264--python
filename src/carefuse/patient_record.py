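"""Fusion of graph-sourced and text-extracted patient data, with provenance.

Produces the unified views a surgery-planning front end presents:
the encounter list (reverse chronological, with ongoing flags and
ICD-10 → disease-class resolution), per-measure measurement series
merged from both structured systems and from clinical notes, the
critical-information summary (smoking/allergy assessments grouped by
status), and a compact surgery-plan summary (latest/min/max per
measure plus the value series).

Every data point carries a SourceRef naming the system or document it
came from; document-sourced items always carry the source text
snippet.  Nothing is deduplicated across sources — identical values
from different systems are presented side by side, distinguishable by
provenance.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field, asdict
from typing import Iterable

from . import ns
from .errors import PatientNotFoundError
from .extraction import VitalExtraction
from .mapping_engine import Literal
from .synthetic_data import FIELD_TO_MEASURE, MEASURE_TO_FIELD
from .text_index import DocumentRecord, Index
from .triple_store import TripleStore, predicate_object_list
from .vocabulary import TermRegistry, disease_for_icd10
from .errors import CodeSyntaxError

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1.0"

_SYSTEM_RANK = {"DIPS": 0, "Metavision": 1, "document": 2}


@dataclass(frozen=True)
class SourceRef:
    """Provenance of one datum: source system, or document plus snippet."""

    system: str                     # "DIPS" | "Metavision" | "document"
    record_id: str
    snippet: str | None = None      # present iff system == "document"
    retrieved_at: str | None = None

    def __post_init__(self):
        if (self.system == "document") != (self.snippet is not None):
            raise ValueError("snippet present iff the source is a document")


@dataclass
class Measurement:
    measure: str
    value: float
    unit: str
    timestamp: _dt.datetime
    provenance: SourceRef

    def to_json(self) -> dict:
        return {"measure": self.measure, "value": self.value,
                "unit": self.unit, "timestamp": self.timestamp.isoformat(),
                "provenance": asdict(self.provenance)}


@dataclass
class Encounter:
    iri: str
    patient: str
    start: _dt.date
    end: _dt.date | None
    title: str | None
    diagnoses: list[tuple[str, str | None]] = field(default_factory=list)
    operations: list[str] = field(default_factory=list)

    @property
    def ongoing(self) -> bool:
        return self.end is None

    def to_json(self) -> dict:
        return {"iri": self.iri, "patient": self.patient,
                "start": self.start.isoformat(),
                "end": self.end.isoformat() if self.end else None,
                "ongoing": self.ongoing, "title": self.title,
                "diagnoses": [{"icd10": c, "disease": d}
                              for c, d in self.diagnoses],
                "operations": list(self.operations)}


@dataclass
class StatusEntry:
    status: str
    timestamp: str
    snippet: str
    doc_id: str


@dataclass
class CriticalInfoSummary:
    """Smoking/allergy assessments grouped by predicted status."""

    smoking: dict[str, list[StatusEntry]] = field(default_factory=dict)
    allergy: dict[str, list[StatusEntry]] = field(default_factory=dict)

    def counts(self, category: str) -> dict[str, int]:
        groups = getattr(self, category)
        return {status: len(entries) for status, entries in groups.items()}

    def to_json(self) -> dict:
        return {
            cat: {
                "counts": self.counts(cat),
                "assessments": {s: [asdict(e) for e in entries]
                                for s, entries in getattr(self, cat).items()},
            }
            for cat in ("smoking", "allergy")
        }


@dataclass
class MeasureSummary:
    latest_value: float
    latest_timestamp: str
    minimum: float
    maximum: float
    values: list[float]    # reverse-chronological value series (sparkline)

    def to_json(self) -> dict:
        return asdict(self)


@dataclass
class MergeResult:
    """Merged per-measure series plus items quarantined for bad timestamps."""

    series: dict[str, list[Measurement]]
    quarantined: list[dict]

    def total(self) -> int:
        return sum(len(v) for v in self.series.values())


# ---------------------------------------------------------------- merging --
def _sort_series(items: list[Measurement]) -> list[Measurement]:
    return sorted(items, key=lambda m: (
        m.timestamp, -_SYSTEM_RANK.get(m.provenance.system, 9),
        m.provenance.record_id), reverse=True)


def merge_measurements(
        structured: Iterable[Measurement],
        extracted: Iterable[tuple[VitalExtraction, DocumentRecord]] = (),
) -> MergeResult:
    """Merge structured rows and note extractions into per-measure series.

    Extracted items become Measurements with a document SourceRef
    carrying the snippet.  Series are reverse chronological; nothing is
    deduplicated.  Items whose timestamp cannot be parsed are
    quarantined with a warning, never silently dropped.
    """
    series: dict[str, list[Measurement]] = {}
    quarantined: list[dict] = []
    for m in structured:
        series.setdefault(m.measure, []).append(m)
    for vital, doc in extracted:
        try:
            ts = doc.parsed_timestamp()
        except ValueError:
            logger.warning("quarantined extraction from %s: bad timestamp %r",
                           doc.doc_id, doc.timestamp)
            quarantined.append({"doc_id": doc.doc_id, "measure": vital.measure,
                                "timestamp": doc.timestamp})
            continue
        series.setdefault(vital.measure, []).append(Measurement(
            measure=vital.measure, value=vital.value, unit=vital.unit,
            timestamp=ts,
            provenance=SourceRef("document", doc.doc_id, vital.snippet)))
    return MergeResult(
        {k: _sort_series(v) for k, v in sorted(series.items())}, quarantined)


def summarize(series: list[Measurement]) -> MeasureSummary | None:
    """Latest/min/max of a series; None for an empty series.

    "Latest" is the maximum timestamp; a timestamp tie resolves to the
    larger value.
    """
    if not series:
        return None
    latest = max(series, key=lambda m: (m.timestamp, m.value))
    return MeasureSummary(
        latest_value=latest.value,
        latest_timestamp=latest.timestamp.isoformat(),
        minimum=min(m.value for m in series),
        maximum=max(m.value for m in series),
        values=[m.value for m in _sort_series(series)])


# -------------------------------------------------------------- structured --
def _literal_value(store: TripleStore, subject: str, predicate: str) -> str | None:
    for t in store.match(subject, predicate, None):
        if isinstance(t.object, Literal):
            return t.object.lexical
    return None


def structured_measurements(patient: str, store: TripleStore,
                            registry: TermRegistry) -> list[Measurement]:
    """Patient's vital-sign rows from the graph, via per-measure link properties."""
    out: list[Measurement] = []
    for measure, (_cls, link_prop, unit) in ns.MEASURE_TYPES.items():
        for t in store.match(patient, link_prop, None):
            miri = t.object
            if not isinstance(miri, str):
                continue
            value = _literal_value(store, miri, ns.AHUS + "measurementValue")
            ts = _literal_value(store, miri, ns.AHUS + "measurementTimestamp")
            u = _literal_value(store, miri, ns.AHUS + "measurementUnit") or unit
            if value is None or ts is None:
                continue
            out.append(Measurement(
                measure=measure, value=float(value), unit=u,
                timestamp=_dt.datetime.fromisoformat(ts),
                provenance=SourceRef(t.source or "DIPS", miri)))
    return out


def document_extractions(docs: Iterable[DocumentRecord]
                         ) -> list[tuple[VitalExtraction, DocumentRecord]]:
    """Reconstruct vital extractions from annotated documents' field pairs."""
    out = []
    for doc in docs:
        for fname, measure in FIELD_TO_MEASURE.items():
            values = doc.extracted.get(fname, [])
            infos = doc.extracted.get(fname.replace("_value", "_info"), [])
            for value, info in zip(values, infos):
                out.append((VitalExtraction(
                    measure=measure, value=float(value), unit="",
                    snippet=info, span=(0, 0), doc_id=doc.doc_id,
                    field_name=fname), doc))
    return out


def list_encounters(patient: str, store: TripleStore,
                    registry: TermRegistry) -> list[Encounter]:
    """Patient's encounters in reverse chronological order of start date."""
    out: list[Encounter] = []
    for t in store.match(None, ns.AHUS + "involvesPatient", patient):
        enc = t.subject
        start = _literal_value(store, enc, ns.AHUS + "encounterStartDate")
        if start is None:
            continue
        end = _literal_value(store, enc, ns.AHUS + "encounterEndDate")
        title = _literal_value(store, enc, ns.AHUS + "encounterTitle")
        diagnoses: list[tuple[str, str | None]] = []
        for tr in store.match(enc, ns.AHUS + "icd10Code", None):
            code = tr.object.lexical if isinstance(tr.object, Literal) else None
            if code:
                try:
                    diagnoses.append((code, disease_for_icd10(code, registry)))
                except CodeSyntaxError:
                    diagnoses.append((code, None))
        operations = [tr.object.lexical
                      for tr in store.match(enc, ns.AHUS + "operationCode", None)
                      if isinstance(tr.object, Literal)]
        out.append(Encounter(
            iri=enc, patient=patient,
            start=_dt.date.fromisoformat(start),
            end=_dt.date.fromisoformat(end) if end else None,
            title=title, diagnoses=sorted(diagnoses),
            operations=sorted(operations)))
    out.sort(key=lambda e: (e.start, e.iri), reverse=True)
    return out


# ------------------------------------------------------------ critical info --
def critical_info(docs: Iterable[DocumentRecord]) -> CriticalInfoSummary:
    """Group annotated status assessments by category and predicted status."""
    summary = CriticalInfoSummary()
    for doc in sorted(docs, key=lambda d: (d.timestamp, d.doc_id), reverse=True):
        for category in ("smoking", "allergy"):
            statuses = doc.extracted.get(f"{category}_status_value", [])
            snippets = doc.extracted.get(f"{category}_status_info", [])
            groups = getattr(summary, category)
            for status, snippet in zip(statuses, snippets):
                groups.setdefault(status, []).append(StatusEntry(
                    status=status, timestamp=doc.timestamp,
                    snippet=snippet, doc_id=doc.doc_id))
    return summary


# -------------------------------------------------------------- plan summary --
@dataclass
class PlanSummary:
    measures: dict[str, MeasureSummary]
    smoking_counts: dict[str, int]
    allergy_counts: dict[str, int]
    latest_allergy_snippet: str | None

    def to_json(self) -> dict:
        return {
            "measures": {k: v.to_json() for k, v in self.measures.items()},
            "smoking_counts": self.smoking_counts,
            "allergy_counts": self.allergy_counts,
            "latest_allergy_snippet": self.latest_allergy_snippet,
        }


def plan_summary(merged: MergeResult,
                 info: CriticalInfoSummary) -> PlanSummary:
    measures = {}
    for measure, series in merged.series.items():
        s = summarize(series)
        if s is not None:
            measures[measure] = s
    latest_allergy = None
    entries = [e for group in info.allergy.values() for e in group]
    if entries:
        latest_allergy = max(entries, key=lambda e: (e.timestamp, e.doc_id)).snippet
    return PlanSummary(
        measures=measures,
        smoking_counts=info.counts("smoking"),
        allergy_counts=info.counts("allergy"),
        latest_allergy_snippet=latest_allergy)


# ------------------------------------------------------------ full assembly --
@dataclass
class PatientRecord:
    patient: str
    administrative: dict
    encounters: list[Encounter]
    measurements: MergeResult
    critical: CriticalInfoSummary
    plan: PlanSummary

    def to_json(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "patient": self.patient,
            "administrative": self.administrative,
            "encounters": [e.to_json() for e in self.encounters],
            "measurements": {
                "series": {k: [m.to_json() for m in v]
                           for k, v in self.measurements.series.items()},
                "quarantined": self.measurements.quarantined,
            },
            "critical_information": self.critical.to_json(),
            "plan_summary": self.plan.to_json(),
        }


class RecordAssembler:
    """Builds patient records on demand and caches them.

    The cache key includes the mutation counters of both backends, so a
    second call with unchanged backends returns the cached object
    without re-querying, and any backend mutation invalidates it.
    """

    def __init__(self, store: TripleStore, index: Index,
                 registry: TermRegistry):
        self.store = store
        self.index = index
        self.registry = registry
        self.query_count = 0
        self._cache: dict[str, tuple[tuple[int, int], PatientRecord]] = {}

    def patient_iri(self, patient_id: str) -> str:
        return f"{ns.DATA}patient/{patient_id}"

    def assemble(self, patient_id: str) -> PatientRecord:
        versions = (self.store.version, self.index.version)
        hit = self._cache.get(patient_id)
        if hit is not None and hit[0] == versions:
            return hit[1]
        record = self._build(patient_id)
        self._cache[patient_id] = (versions, record)
        return record

    def _build(self, patient_id: str) -> PatientRecord:
        self.query_count += 1
        iri = self.patient_iri(patient_id)
        pairs = predicate_object_list(iri, self.store)
        if not pairs:
            raise PatientNotFoundError(patient_id)

        admin: dict[str, object] = {"id": patient_id, "iri": iri}
        admin_props = {
            ns.FOAF + "name": "name",
            ns.FOAF + "gender": "gender",
            ns.AHUS + "socialSecurityNumber": "ssn",
            ns.AHUS + "dateOfBirth": "birth_date",
        }
        for pred, obj in pairs:
            key = admin_props.get(pred)
            if key and isinstance(obj, Literal) and key not in admin:
                admin[key] = obj.lexical

        docs = [d for d in self.index.docs.values()
                if d.patient_id == patient_id]
        merged = merge_measurements(
            structured_measurements(iri, self.store, self.registry),
            document_extractions(docs))
        info = critical_info(docs)
        return PatientRecord(
            patient=iri,
            administrative=admin,
            encounters=list_encounters(iri, self.store, self.registry),
            measurements=merged,
            critical=info,
            plan=plan_summary(merged, info))
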