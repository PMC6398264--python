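"""Pattern-based mining of clinical notes for vitals and critical information.

A per-document transformer step runs a pack of regular expressions over
the note text and populates paired value/snippet fields in the
document's ``extracted`` map (e.g. ``blood_pulse_value`` holds the
number, ``blood_pulse_info`` holds the verbatim source fragment).

The patterns tolerate optional colons and whitespace, accept alternative
terms and abbreviations (temperatur/temp/t, BT for blood pressure), and
normalize decimal commas.  Every vital measure carries an inclusive
plausibility range; out-of-range values are discarded and logged rather
than emitted.  Smoking and allergy statements get a status label, with
negation, past tense and question/recommendation forms handled by
pattern precedence: uncertain (questions, recommendations) outranks
negation, which outranks "former", which outranks plain affirmation,
whenever matched spans overlap.

Patterns live in editable YAML packs, not in code, so that clinical
sites can retune them; a Norwegian pack is primary and an English pack
ships for testing and readability.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .errors import PatternPackError
from .text_index import DocumentRecord

logger = logging.getLogger(__name__)

SMOKING_STATUSES = ("positive", "negative", "former", "uncertain")
ALLERGY_STATUSES = ("positive", "negative", "uncertain")

_FLAGS = re.IGNORECASE | re.UNICODE


@dataclass
class ExtractorSpec:
    """Patterns and constraints for one vital-sign measure."""

    measure: str
    patterns: list[str]
    synonyms: list[str]
    value_range: tuple[float, float]
    unit: str
    value_field: str
    info_field: str
    compiled: list[re.Pattern] = field(default_factory=list)

    def __post_init__(self):
        lo, hi = self.value_range
        if not lo < hi:
            raise PatternPackError(
                f"{self.measure}: range must satisfy min < max")
        if not self.compiled:
            self.compiled = [re.compile(p, _FLAGS) for p in self.patterns]
        for pat in self.compiled:
            if "value" not in pat.groupindex:
                raise PatternPackError(
                    f"{self.measure}: pattern {pat.pattern!r} lacks a "
                    "(?P<value>...) group")


@dataclass
class BloodPressureSpec:
    """Paired systolic/diastolic extraction from NNN/NNN forms."""

    patterns: list[str]
    synonyms: list[str]
    systolic_range: tuple[float, float]
    diastolic_range: tuple[float, float]
    unit: str
    systolic_field: str
    systolic_info_field: str
    diastolic_field: str
    diastolic_info_field: str
    compiled: list[re.Pattern] = field(default_factory=list)

    def __post_init__(self):
        if not self.compiled:
            self.compiled = [re.compile(p, _FLAGS) for p in self.patterns]
        for pat in self.compiled:
            for group in ("systolic", "diastolic"):
                if group not in pat.groupindex:
                    raise PatternPackError(
                        f"blood pressure pattern {pat.pattern!r} lacks "
                        f"(?P<{group}>...)")


@dataclass
class StatusPatternGroup:
    """All patterns assigning one status label, with overlap precedence."""

    label: str
    priority: int
    patterns: list[str]
    compiled: list[re.Pattern] = field(default_factory=list)

    def __post_init__(self):
        if not self.compiled:
            self.compiled = [re.compile(p, _FLAGS) for p in self.patterns]
        for pat in self.compiled:
            if pat.groups < 1:
                raise PatternPackError(
                    f"status pattern {pat.pattern!r} lacks the parenthesized "
                    "key-snippet group")


@dataclass
class PatternPack:
    language: str
    vitals: list[ExtractorSpec]
    blood_pressure: BloodPressureSpec
    smoking: list[StatusPatternGroup]
    allergy: list[StatusPatternGroup]


@dataclass
class VitalExtraction:
    """One extracted vital-sign data point; snippet == text[span]."""

    measure: str
    value: float
    unit: str
    snippet: str
    span: tuple[int, int]
    doc_id: str = ""
    field_name: str = ""
    info_field_name: str = ""


@dataclass
class StatusExtraction:
    """One smoking/allergy assessment extracted from a note."""

    category: str   # "smoking" | "allergy"
    status: str
    snippet: str
    span: tuple[int, int]
    doc_id: str = ""
    allergen: str | None = None


# ------------------------------------------------------------------ loading --
def load_pattern_pack(path: str | Path | None = None,
                      language: str = "no") -> PatternPack:
    """Load a YAML pattern pack; default to the packaged pack for `language`."""
    if path is None:
        from .vocabulary import packaged_path
        path = packaged_path(f"patterns_{language}.yaml")
    try:
        raw = yaml.safe_load(Path(path).read_text("utf-8"))
    except yaml.YAMLError as exc:
        raise PatternPackError(f"{path}: invalid YAML: {exc}") from exc

    vitals = []
    seen_fields: set[str] = set()
    for item in raw.get("vitals", []):
        spec = ExtractorSpec(
            measure=item["measure"],
            patterns=item["patterns"],
            synonyms=item.get("synonyms", []),
            value_range=tuple(item["range"]),
            unit=item["unit"],
            value_field=item["value_field"],
            info_field=item["info_field"],
        )
        for name in (spec.value_field, spec.info_field):
            if name in seen_fields:
                raise PatternPackError(f"duplicate field name {name!r}")
            seen_fields.add(name)
        vitals.append(spec)

    bp_raw = raw["blood_pressure"]
    bp = BloodPressureSpec(
        patterns=bp_raw["patterns"],
        synonyms=bp_raw.get("synonyms", []),
        systolic_range=tuple(bp_raw["systolic_range"]),
        diastolic_range=tuple(bp_raw["diastolic_range"]),
        unit=bp_raw["unit"],
        systolic_field=bp_raw["systolic_field"],
        systolic_info_field=bp_raw["systolic_info_field"],
        diastolic_field=bp_raw["diastolic_field"],
        diastolic_info_field=bp_raw["diastolic_info_field"],
    )

    def status_groups(category: str, allowed: tuple[str, ...]):
        groups = []
        for item in raw["statuses"][category]:
            if item["label"] not in allowed:
                raise PatternPackError(
                    f"{category}: label {item['label']!r} not in {allowed}")
            groups.append(StatusPatternGroup(
                label=item["label"], priority=int(item["priority"]),
                patterns=item["patterns"]))
        return groups

    return PatternPack(
        language=raw.get("language", "no"),
        vitals=vitals,
        blood_pressure=bp,
        smoking=status_groups("smoking", SMOKING_STATUSES),
        allergy=status_groups("allergy", ALLERGY_STATUSES),
    )


# --------------------------------------------------------------- extraction --
def _parse_value(lexical: str) -> float:
    return float(lexical.replace(",", "."))


def _overlaps(span: tuple[int, int], accepted: list[tuple[int, int]]) -> bool:
    s, e = span
    return any(s < ae and a_s < e for a_s, ae in accepted)


def extract_vitals(text: str,
                   specs: list[ExtractorSpec]) -> list[VitalExtraction]:
    """All non-overlapping vital matches, in document order.

    Out-of-range values are discarded (and logged); overlapping matches
    are resolved first-come in document order, longer match first.
    """
    candidates: list[VitalExtraction] = []
    for spec in specs:
        lo, hi = spec.value_range
        for pat in spec.compiled:
            for m in pat.finditer(text):
                value = _parse_value(m.group("value"))
                if not lo <= value <= hi:
                    logger.info("discarded out-of-range %s value %s in %r",
                                spec.measure, value, m.group(0))
                    continue
                candidates.append(VitalExtraction(
                    measure=spec.measure, value=value, unit=spec.unit,
                    snippet=m.group(0), span=m.span(),
                    field_name=spec.value_field,
                    info_field_name=spec.info_field))
    candidates.sort(key=lambda v: (v.span[0], -(v.span[1] - v.span[0])))
    accepted: list[VitalExtraction] = []
    spans: list[tuple[int, int]] = []
    for cand in candidates:
        if _overlaps(cand.span, spans):
            continue
        accepted.append(cand)
        spans.append(cand.span)
    return accepted


def extract_blood_pressure(text: str,
                           spec: BloodPressureSpec) -> list[VitalExtraction]:
    """Paired systolic/diastolic extractions from "BT 120/80"-style forms.

    Both components are range-checked; an implausible pair where the
    systolic value does not exceed the diastolic discards both.
    """
    out: list[VitalExtraction] = []
    for pat in spec.compiled:
        for m in pat.finditer(text):
            sys_v = _parse_value(m.group("systolic"))
            dia_v = _parse_value(m.group("diastolic"))
            lo_s, hi_s = spec.systolic_range
            lo_d, hi_d = spec.diastolic_range
            if sys_v <= dia_v:
                logger.info("discarded implausible blood-pressure pair %r",
                            m.group(0))
                continue
            if not lo_s <= sys_v <= hi_s or not lo_d <= dia_v <= hi_d:
                logger.info("discarded out-of-range blood pressure %r",
                            m.group(0))
                continue
            common = dict(unit=spec.unit, snippet=m.group(0), span=m.span())
            out.append(VitalExtraction(
                measure="systolic_bp", value=sys_v,
                field_name=spec.systolic_field,
                info_field_name=spec.systolic_info_field, **common))
            out.append(VitalExtraction(
                measure="diastolic_bp", value=dia_v,
                field_name=spec.diastolic_field,
                info_field_name=spec.diastolic_info_field, **common))
    out.sort(key=lambda v: (v.span[0], v.measure != "systolic_bp"))
    return out


def _classify(text: str, groups: list[StatusPatternGroup],
              category: str) -> list[StatusExtraction]:
    candidates: list[tuple[int, StatusExtraction, tuple[int, int]]] = []
    for group in groups:
        for pat in group.compiled:
            for m in pat.finditer(text):
                snippet = m.group(1)
                allergen = None
                if "allergen" in pat.groupindex:
                    allergen = m.group("allergen")
                candidates.append((
                    group.priority,
                    StatusExtraction(
                        category=category, status=group.label,
                        snippet=snippet, span=m.span(1), allergen=allergen),
                    m.span()))
    # precedence: priority desc, then longer match, then document order
    candidates.sort(key=lambda c: (-c[0], -(c[2][1] - c[2][0]), c[2][0]))
    accepted: list[StatusExtraction] = []
    spans: list[tuple[int, int]] = []
    for _prio, extraction, full_span in candidates:
        if _overlaps(full_span, spans):
            continue
        accepted.append(extraction)
        spans.append(full_span)
    accepted.sort(key=lambda e: e.span[0])
    return accepted


def classify_smoking(text: str, pack: PatternPack) -> list[StatusExtraction]:
    """Label every smoking-related snippet: positive/negative/former/uncertain."""
    return _classify(text, pack.smoking, "smoking")


def classify_allergy(text: str, pack: PatternPack) -> list[StatusExtraction]:
    """Label every allergy-related snippet: positive/negative/uncertain."""
    return _classify(text, pack.allergy, "allergy")


def extract_all(text: str, pack: PatternPack) -> tuple[
        list[VitalExtraction], list[StatusExtraction]]:
    """Run the full transformer set over one text."""
    bp = extract_blood_pressure(text, pack.blood_pressure)
    bp_spans = [v.span for v in bp[::2]]  # one span per pair
    vitals = [v for v in extract_vitals(text, pack.vitals)
              if not _overlaps(v.span, bp_spans)]
    merged = sorted(vitals + bp, key=lambda v: v.span[0])
    statuses = classify_smoking(text, pack) + classify_allergy(text, pack)
    return merged, statuses


def annotate_document(doc: DocumentRecord, pack: PatternPack) -> DocumentRecord:
    """Populate the document's extracted map from its text (idempotent).

    For every hit the value field receives the value and the info field
    the verbatim snippet, as ordered lists; the text is untouched.
    """
    vitals, statuses = extract_all(doc.text, pack)
    extracted: dict[str, list] = {}
    for v in vitals:
        v.doc_id = doc.doc_id
        extracted.setdefault(v.field_name, []).append(v.value)
        extracted.setdefault(v.info_field_name, []).append(v.snippet)
    for s in statuses:
        s.doc_id = doc.doc_id
        extracted.setdefault(f"{s.category}_status_value", []).append(s.status)
        extracted.setdefault(f"{s.category}_status_info", []).append(s.snippet)
        if s.allergen:
            extracted.setdefault("allergy_allergen", []).append(s.allergen)
    return replace(doc, extracted=extracted)


def annotate_corpus(docs: list[DocumentRecord],
                    pack: PatternPack) -> list[DocumentRecord]:
    return [annotate_document(d, pack) for d in docs]
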