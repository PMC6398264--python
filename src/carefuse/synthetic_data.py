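"""Synthetic study substrate: two relational databases and a labeled corpus.

Real hospital data cannot ship with this package, so every other module
is exercised against synthetic stand-ins that emulate the roles of the
two structured sources (an EHR system holding administrative data,
encounters tagged with ICD-10 and operation codes, and vital-sign rows;
and a physician-order-entry system holding administrative data and
vital-sign rows) plus a corpus of templated Norwegian-style clinical
notes with known planted labels.

Scale defaults mirror the pilot setting: 10 patients, tens of notes per
patient (hundreds for some).  All randomness flows through one
fixed-algorithm generator (PCG64), so identical seeds give identical
outputs across platforms.  Social security numbers have a valid-looking
11-digit structure but a deliberately invalid checksum, so accidental
realism is impossible.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import sqlite3
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import AlignmentError, ConfigError
from .text_index import DocumentRecord, write_corpus

MEASURE_KEYS = ("pulse", "temperature", "systolic_bp", "diastolic_bp",
                "weight", "height", "bmi", "asa")

#: extracted-field name -> measure key (the shipped packs' field layout)
FIELD_TO_MEASURE = {
    "blood_pulse_value": "pulse",
    "body_temperature_value": "temperature",
    "systolic_bp_value": "systolic_bp",
    "diastolic_bp_value": "diastolic_bp",
    "body_weight_value": "weight",
    "body_height_value": "height",
    "bmi_value": "bmi",
    "asa_value": "asa",
}
MEASURE_TO_FIELD = {v: k for k, v in FIELD_TO_MEASURE.items()}


@dataclass
class SimConfig:
    """Knobs of the generator; defaults are the study conditions."""

    seed: int = 1
    n_patients: int = 10
    encounters_per_patient: tuple[int, int] = (1, 6)
    notes_per_patient: tuple[int, int] = (20, 90)
    #: probability that a note mentions each measure
    mention_rates: dict = field(default_factory=lambda: {
        "pulse": 0.30, "temperature": 0.30, "blood_pressure": 0.30,
        "weight": 0.20, "height": 0.15, "bmi": 0.15, "asa": 0.10,
    })
    #: probability that a note carries a smoking / allergy statement
    smoking_rate: float = 0.35
    allergy_rate: float = 0.30
    #: conditional status distributions given a statement is present
    smoking_distribution: dict = field(default_factory=lambda: {
        "positive": 0.25, "negative": 0.35, "former": 0.15, "uncertain": 0.25,
    })
    allergy_distribution: dict = field(default_factory=lambda: {
        "positive": 0.35, "negative": 0.45, "uncertain": 0.20,
    })
    #: probability of corrupting a planted keyword (typo noise)
    noise_rate: float = 0.0
    #: probability that a decimal value is written with a comma
    decimal_comma_rate: float = 0.4
    date_window: tuple[str, str] = ("2013-01-01", "2016-12-31")

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        for name in ("encounters_per_patient", "notes_per_patient"):
            lo, hi = getattr(self, name)
            if not 0 <= lo < hi:
                raise ConfigError(f"{name} range must be non-degenerate")
        for name in ("smoking_rate", "allergy_rate", "noise_rate",
                     "decimal_comma_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        for name in ("smoking_distribution", "allergy_distribution"):
            dist = getattr(self, name)
            if any(not 0 <= p <= 1 for p in dist.values()):
                raise ConfigError(f"{name} probabilities must be in [0, 1]")
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ConfigError(f"{name} must sum to 1")
        for p in self.mention_rates.values():
            if not 0.0 <= p <= 1.0:
                raise ConfigError("mention rates must be in [0, 1]")
        start, end = self.date_window
        if not start < end:
            raise ConfigError("date window must be non-degenerate")

    def sha256(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()


@dataclass
class GroundTruth:
    """Planted labels: per-document extractions and per-patient series."""

    vitals: dict[str, list] = field(default_factory=dict)       # doc -> [(measure, value)]
    statuses: dict[str, list] = field(default_factory=dict)     # doc -> [(category, status)]
    measurements: dict[str, list] = field(default_factory=dict) # patient -> rows
    encounters: dict[str, list] = field(default_factory=dict)   # patient -> rows

    def to_json(self) -> dict:
        return asdict(self)

    @classmethod
    def from_json(cls, obj: dict) -> "GroundTruth":
        gt = cls(**obj)
        gt.vitals = {k: [tuple(x) for x in v] for k, v in gt.vitals.items()}
        gt.statuses = {k: [tuple(x) for x in v] for k, v in gt.statuses.items()}
        return gt


# -------------------------------------------------------------------- names --
_FIRST = ["Kari", "Ola", "Ingrid", "Lars", "Anne", "Per", "Silje", "Nils",
          "Hanne", "Erik", "Mari", "Jon", "Astrid", "Bjørn", "Liv", "Arne"]
_LAST = ["Nordmann", "Hansen", "Johansen", "Olsen", "Larsen", "Andersen",
         "Pedersen", "Nilsen", "Kristiansen", "Jensen", "Karlsen", "Berg"]

_ENCOUNTER_TITLES = [
    "Innleggelse gastrokirurgisk avdeling", "Dagkirurgisk inngrep",
    "Poliklinisk konsultasjon", "Akutt innleggelse",
    "Preoperativ vurdering", "Postoperativ kontroll",
    "Anestesitilsyn", "Telefonkonsultasjon",
]
_OPERATION_CODES = ["JEA00", "JAB10", "JFB30", "JKA20", "NGD05", "KED10"]
_DOC_TYPES = ["andre", "innkomstjournal", "epikrise", "operasjonsnotat",
              "poliklinisk notat", "sykepleienotat"]
_DOC_TYPE_WEIGHTS = [0.30, 0.15, 0.15, 0.10, 0.15, 0.15]

_FILLER = [
    "Pasienten kom til planlagt kontroll.",
    "Operasjonen gikk som planlagt.",
    "Ingen komplikasjoner under inngrepet.",
    "Pasienten er i god allmenntilstand.",
    "Såret gror fint.",
    "Videre oppfølging hos fastlege.",
    "Pasienten informeres om videre forløp.",
    "Mobiliseres etter planen.",
    "God effekt av smertelindring.",
    "Pasienten samtykker til inngrepet.",
]

# sentence templates per measure; {v} receives the value
_VITAL_TEMPLATES = {
    "pulse": ["Puls: {v}.", "puls {v}", "Pulsen {v} ved kontroll."],
    "temperature": ["Temp {v}.", "Temperatur: {v}.", "t {v}"],
    "weight": ["Vekt: {v} kg.", "vekt {v}", "Vekten {v} kg ved innkomst."],
    "height": ["Høyde: {v} cm.", "høyde {v}"],
    "bmi": ["BMI: {v}.", "BMI {v} beregnet."],
    "asa": ["ASA {v}.", "ASA-klasse {v}.", "asa {v}"],
}
_BP_TEMPLATES = ["BT {s}/{d}.", "Blodtrykk: {s}/{d}.", "BT: {s}/{d} målt."]

_SMOKING_TEMPLATES = {
    "positive": ["Pasienten røyker daglig.", "Røyker 10 sigaretter om dagen.",
                 "Dagligrøyker gjennom mange år."],
    "negative": ["Røyker ikke.", "Pasienten er ikke-røyker.",
                 "Har aldri røykt."],
    "former": ["Tidligere røyker.", "Eks-røyker.",
               "Pasienten sluttet å røyke i fjor."],
    "uncertain": ["Røyker du? Spurt ved innkomst.",
                  "Røykeslutt anbefales før operasjonen.",
                  "Røykestatus? Ikke dokumentert."],
}
_ALLERGENS = ["penicillin", "latex", "morfin", "nøtter", "pollen"]
_ALLERGY_TEMPLATES = {
    "positive": ["Allergi mot {a}.", "Pasienten er allergisk mot {a}."],
    "negative": ["Ingen kjente allergier.", "Ingen allergier.",
                 "Pasienten er ikke allergisk."],
    "uncertain": ["Allergier? Ikke avklart.",
                  "Kan ikke utelukke allergi.",
                  "Mulig allergi mot kontrastmiddel."],
}


def _rng(config: SimConfig) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(config.seed))


def _rand_date(rng, window: tuple[str, str]) -> _dt.date:
    start = _dt.date.fromisoformat(window[0])
    end = _dt.date.fromisoformat(window[1])
    return start + _dt.timedelta(days=int(rng.integers(0, (end - start).days + 1)))


def _rand_datetime(rng, window: tuple[str, str]) -> _dt.datetime:
    d = _rand_date(rng, window)
    return _dt.datetime(d.year, d.month, d.day,
                        int(rng.integers(7, 22)), int(rng.integers(0, 60)))


def _ssn(rng, birth_date: _dt.date) -> str:
    """11-digit national-id lookalike with an invalid checksum by construction."""
    individual = int(rng.integers(0, 1000))
    d9 = f"{birth_date:%d%m%y}{individual:03d}"
    digits = [int(c) for c in d9]
    w1 = [3, 7, 6, 1, 8, 9, 4, 5, 2]
    k1 = (11 - sum(d * w for d, w in zip(digits, w1)) % 11) % 11
    if k1 == 10:
        k1 = 0  # would be invalid anyway; keep a digit
    w2 = [5, 4, 3, 2, 7, 6, 5, 4, 3, 2]
    k2 = (11 - sum(d * w for d, w in zip(digits + [k1], w2)) % 11) % 11
    if k2 == 10:
        k2 = 0
    return f"{d9}{k1}{(k2 + 1) % 10}"  # +1 breaks the second check digit


def _typo(rng, word: str) -> str:
    """Transpose two adjacent letters (keyword corruption noise)."""
    if len(word) < 4:
        return word
    i = int(rng.integers(1, len(word) - 2))
    return word[:i] + word[i + 1] + word[i] + word[i + 2:]


def _fmt_decimal(rng, value: float, comma_rate: float) -> str:
    text = f"{value:.1f}" if value != int(value) else str(int(value))
    if "." in text and rng.random() < comma_rate:
        text = text.replace(".", ",")
    return text


def _pick(rng, seq):
    return seq[int(rng.integers(0, len(seq)))]


def _weighted(rng, items, weights) -> str:
    r = rng.random()
    acc = 0.0
    for item, w in zip(items, weights):
        acc += w
        if r < acc:
            return item
    return items[-1]


# ---------------------------------------------------------------- databases --
_SCHEMA_DIPS = """
CREATE TABLE patient (
  id INTEGER PRIMARY KEY, ssn TEXT, name TEXT, birth_date TEXT, gender TEXT);
CREATE TABLE encounter (
  id INTEGER PRIMARY KEY, patient_id INTEGER NOT NULL REFERENCES patient(id),
  start_date TEXT NOT NULL, end_date TEXT, title TEXT,
  icd10_code TEXT, operation_code TEXT);
CREATE TABLE measurement (
  id INTEGER PRIMARY KEY, patient_id INTEGER NOT NULL REFERENCES patient(id),
  type TEXT NOT NULL, value REAL NOT NULL, unit TEXT, ts TEXT NOT NULL);
"""

_SCHEMA_MV = """
CREATE TABLE patient (
  id INTEGER PRIMARY KEY, name TEXT, birth_date TEXT);
CREATE TABLE measurement (
  id INTEGER PRIMARY KEY, patient_id INTEGER NOT NULL REFERENCES patient(id),
  type TEXT NOT NULL, value REAL NOT NULL, unit TEXT, ts TEXT NOT NULL);
"""

_MEASURE_VALUE_RANGES = {
    "pulse": (55, 110), "temperature": (36.0, 39.5),
    "systolic_bp": (95, 180), "diastolic_bp": (55, 95),
    "weight": (45, 120), "height": (150, 200), "bmi": (17, 38), "asa": (1, 4),
}
_MEASURE_UNITS = {
    "pulse": "bpm", "temperature": "C", "systolic_bp": "mmHg",
    "diastolic_bp": "mmHg", "weight": "kg", "height": "cm",
    "bmi": "kg/m2", "asa": "ASA",
}
_MV_MEASURES = ("pulse", "temperature", "systolic_bp", "diastolic_bp",
                "weight", "asa")


def _measure_value(rng, measure: str) -> float:
    lo, hi = _MEASURE_VALUE_RANGES[measure]
    if measure in ("temperature",):
        return round(float(rng.uniform(lo, hi)), 1)
    return float(rng.integers(lo, hi + 1))


def _icd10_codes() -> list[str]:
    from .vocabulary import load_icd10_xrefs, packaged_path
    return sorted(load_icd10_xrefs(packaged_path("icd10_xref.tsv")))


def generate_databases(config: SimConfig,
                       out_dir: str | Path) -> tuple[Path, Path, GroundTruth]:
    """Write the two SQLite files; returns paths and the structured truth."""
    config.validate()
    rng = _rng(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dips_path = out_dir / "dips.sqlite"
    mv_path = out_dir / "metavision.sqlite"
    for p in (dips_path, mv_path):
        if p.exists():
            p.unlink()

    truth = GroundTruth()
    codes = _icd10_codes()

    dips = sqlite3.connect(dips_path)
    mv = sqlite3.connect(mv_path)
    dips.executescript(_SCHEMA_DIPS)
    mv.executescript(_SCHEMA_MV)

    enc_id = 0
    meas_id = {"DIPS": 0, "Metavision": 0}
    for pid in range(1, config.n_patients + 1):
        birth = _dt.date(int(rng.integers(1940, 2000)),
                         int(rng.integers(1, 13)), int(rng.integers(1, 29)))
        name = f"{_pick(rng, _FIRST)} {_pick(rng, _LAST)}"
        gender = _pick(rng, ["female", "male"])
        dips.execute("INSERT INTO patient VALUES (?,?,?,?,?)",
                     (pid, _ssn(rng, birth), name, birth.isoformat(), gender))
        mv.execute("INSERT INTO patient VALUES (?,?,?)",
                   (pid, name, birth.isoformat()))

        truth.encounters[str(pid)] = []
        lo, hi = config.encounters_per_patient
        for _ in range(int(rng.integers(lo, hi + 1))):
            enc_id += 1
            start = _rand_date(rng, config.date_window)
            ongoing = rng.random() < 0.15
            end = None if ongoing else (
                start + _dt.timedelta(days=int(rng.integers(0, 21))))
            title = _pick(rng, _ENCOUNTER_TITLES)
            icd = _pick(rng, codes) if rng.random() < 0.8 else None
            op = _pick(rng, _OPERATION_CODES) if rng.random() < 0.5 else None
            dips.execute("INSERT INTO encounter VALUES (?,?,?,?,?,?,?)",
                         (enc_id, pid, start.isoformat(),
                          end.isoformat() if end else None, title, icd, op))
            truth.encounters[str(pid)].append({
                "id": enc_id, "start": start.isoformat(),
                "end": end.isoformat() if end else None,
                "title": title, "icd10": icd, "operation": op})

        truth.measurements[str(pid)] = []
        for system, conn, measures in (
                ("DIPS", dips, MEASURE_KEYS),
                ("Metavision", mv, _MV_MEASURES)):
            for measure in measures:
                for _ in range(int(rng.integers(0, 4))):
                    meas_id[system] += 1
                    value = _measure_value(rng, measure)
                    ts = _rand_datetime(rng, config.date_window)
                    conn.execute(
                        "INSERT INTO measurement VALUES (?,?,?,?,?,?)",
                        (meas_id[system], pid, measure, value,
                         _MEASURE_UNITS[measure], ts.isoformat()))
                    truth.measurements[str(pid)].append({
                        "id": meas_id[system], "system": system,
                        "type": measure, "value": value,
                        "unit": _MEASURE_UNITS[measure],
                        "ts": ts.isoformat()})

    dips.commit()
    mv.commit()
    dips.close()
    mv.close()
    return dips_path, mv_path, truth


# -------------------------------------------------------------------- notes --
def _vital_sentence(rng, measure: str, config: SimConfig) -> tuple[str, list]:
    """Realize one vital mention; returns (sentence, truth pairs)."""
    if measure == "blood_pressure":
        s = int(rng.integers(95, 181))
        d = int(rng.integers(55, min(s - 10, 100) + 1))
        template = _pick(rng, _BP_TEMPLATES)
        return (template.format(s=s, d=d),
                [("systolic_bp", float(s)), ("diastolic_bp", float(d))])
    value = _measure_value(rng, measure)
    template = _pick(rng, _VITAL_TEMPLATES[measure])
    if isinstance(value, float) and value != int(value):
        lexical = _fmt_decimal(rng, value, config.decimal_comma_rate)
    else:
        lexical = str(int(value))
        value = float(value)
    return template.format(v=lexical), [(measure, float(str(value)))]


def generate_notes(config: SimConfig) -> tuple[list[DocumentRecord], GroundTruth]:
    """Build the templated note corpus with its planted ground truth.

    With ``noise_rate`` 0 every planted item is recoverable verbatim by
    the shipped Norwegian pattern pack; noise corrupts planted keywords
    (recall degradation becomes measurable, not asserted).
    """
    config.validate()
    rng = _rng(config)
    truth = GroundTruth()
    docs: list[DocumentRecord] = []

    for pid in range(1, config.n_patients + 1):
        lo, hi = config.notes_per_patient
        n_notes = int(rng.integers(lo, hi + 1))
        for k in range(n_notes):
            doc_id = f"doc-{pid}-{k + 1}"
            sentences = [_pick(rng, _FILLER)]
            planted_vitals: list = []
            planted_statuses: list = []

            for measure, rate in sorted(config.mention_rates.items()):
                if rng.random() >= rate:
                    continue
                sentence, pairs = _vital_sentence(rng, measure, config)
                if config.noise_rate and rng.random() < config.noise_rate:
                    head, _, tail = sentence.partition(" ")
                    sentence = _typo(rng, head) + " " + tail
                sentences.append(sentence)
                planted_vitals.extend(pairs)

            if rng.random() < config.smoking_rate:
                status = _weighted(rng, list(config.smoking_distribution),
                                   list(config.smoking_distribution.values()))
                sentence = _pick(rng, _SMOKING_TEMPLATES[status])
                if config.noise_rate and rng.random() < config.noise_rate:
                    head, _, tail = sentence.partition(" ")
                    sentence = _typo(rng, head) + " " + tail
                sentences.append(sentence)
                planted_statuses.append(("smoking", status))

            if rng.random() < config.allergy_rate:
                status = _weighted(rng, list(config.allergy_distribution),
                                   list(config.allergy_distribution.values()))
                template = _pick(rng, _ALLERGY_TEMPLATES[status])
                sentence = template.format(a=_pick(rng, _ALLERGENS))
                if config.noise_rate and rng.random() < config.noise_rate:
                    head, _, tail = sentence.partition(" ")
                    sentence = _typo(rng, head) + " " + tail
                sentences.append(sentence)
                planted_statuses.append(("allergy", status))

            sentences.append(_pick(rng, _FILLER))
            docs.append(DocumentRecord(
                doc_id=doc_id, patient_id=str(pid),
                doc_type=_weighted(rng, _DOC_TYPES, _DOC_TYPE_WEIGHTS),
                timestamp=_rand_datetime(rng, config.date_window).isoformat(),
                text=" ".join(sentences)))
            truth.vitals[doc_id] = planted_vitals
            truth.statuses[doc_id] = planted_statuses
    return docs, truth


# ------------------------------------------------------- search re-staging --
def generate_keyword_corpus(seed: int, n_matching: int = 36,
                            n_plain: int = 50, n_other_type: int = 40,
                            keywords: tuple[str, str] = ("blod", "bt"),
                            matching_doc_type: str = "andre"
                            ) -> list[DocumentRecord]:
    """Corpus where exactly ``n_matching`` documents of the given type
    contain one of the keywords — a synthetic re-staging of a keyword
    search over a document archive.
    """
    from .text_index import analyze

    rng = np.random.Generator(np.random.PCG64(seed))
    key_sentences = [
        "Det ble påvist blod i urinen.",
        "Pasienten har blod i avføringen.",
        "Kontroll av BT i morgen.",
        "BT stabilt gjennom natten.",
    ]
    docs: list[DocumentRecord] = []
    window = ("2014-01-01", "2016-12-31")

    def ts() -> str:
        return _rand_datetime(rng, window).isoformat()

    for i in range(n_matching):
        text = f"{_pick(rng, _FILLER)} {_pick(rng, key_sentences)} {_pick(rng, _FILLER)}"
        docs.append(DocumentRecord(f"match-{i}", str(int(rng.integers(1, 11))),
                                   matching_doc_type, ts(), text))
    for i in range(n_plain):
        text = f"{_pick(rng, _FILLER)} {_pick(rng, _FILLER)}"
        docs.append(DocumentRecord(f"plain-{i}", str(int(rng.integers(1, 11))),
                                   matching_doc_type, ts(), text))
    other_types = [t for t in _DOC_TYPES if t != matching_doc_type]
    for i in range(n_other_type):
        text = f"{_pick(rng, _FILLER)} {_pick(rng, key_sentences)}"
        docs.append(DocumentRecord(f"other-{i}", str(int(rng.integers(1, 11))),
                                   _pick(rng, other_types), ts(), text))

    targets = {t for kw in keywords for t in analyze(kw)}
    for doc in docs:
        tokens = set(analyze(doc.text))
        is_match = bool(tokens & targets)
        should_match = doc.doc_id.startswith("match-") or doc.doc_id.startswith("other-")
        assert is_match == should_match, doc.doc_id
    return docs


def generate_status_profile_corpus(
        patient_id: str, counts: dict[str, int], seed: int = 7,
        category: str = "smoking") -> list[DocumentRecord]:
    """Notes for one patient with an exact per-status breakdown.

    Re-stages a critical-information profile (e.g. 7 non-smoker,
    9 uncertain, 1 ex-smoker documents) with synthetic text.
    """
    templates = _SMOKING_TEMPLATES if category == "smoking" else _ALLERGY_TEMPLATES
    rng = np.random.Generator(np.random.PCG64(seed))
    docs = []
    i = 0
    for status, n in sorted(counts.items()):
        for _ in range(n):
            i += 1
            template = _pick(rng, templates[status])
            text = f"{_pick(rng, _FILLER)} {template.format(a=_pick(rng, _ALLERGENS))}"
            docs.append(DocumentRecord(
                f"status-{i}", patient_id, _pick(rng, _DOC_TYPES),
                _rand_datetime(rng, ("2015-01-01", "2016-12-31")).isoformat(),
                text))
    return docs


# --------------------------------------------------------------- evaluation --
def evaluate_extraction(annotated_docs, truth: GroundTruth):
    """Per-field precision/recall of the annotations against planted truth.

    Vitals match exactly on (measure, value) per document; statuses on
    (category, status) per document.  Precision is NaN ("n/a") when
    nothing was extracted for a field.
    """
    import pandas as pd

    doc_ids = {d.doc_id for d in annotated_docs}
    truth_ids = set(truth.vitals) | set(truth.statuses)
    if truth_ids and not doc_ids <= truth_ids:
        raise AlignmentError("annotated corpus contains documents missing "
                             "from the ground truth")

    def multiset(items):
        out: dict = {}
        for item in items:
            out[item] = out.get(item, 0) + 1
        return out

    keys = ([("vital", m) for m in MEASURE_KEYS]
            + [("status", ("smoking", s)) for s in
               ("positive", "negative", "former", "uncertain")]
            + [("status", ("allergy", s)) for s in
               ("positive", "negative", "uncertain")])
    counters = {k: {"tp": 0, "fp": 0, "fn": 0} for k in keys}

    for doc in annotated_docs:
        planted_v = multiset(tuple(x) for x in truth.vitals.get(doc.doc_id, []))
        got_v: dict = {}
        for fname, measure in FIELD_TO_MEASURE.items():
            for value in doc.extracted.get(fname, []):
                key = (measure, float(value))
                got_v[key] = got_v.get(key, 0) + 1
        for measure in MEASURE_KEYS:
            p = {k: v for k, v in planted_v.items() if k[0] == measure}
            g = {k: v for k, v in got_v.items() if k[0] == measure}
            tp = sum(min(v, g.get(k, 0)) for k, v in p.items())
            counters[("vital", measure)]["tp"] += tp
            counters[("vital", measure)]["fp"] += sum(g.values()) - tp
            counters[("vital", measure)]["fn"] += sum(p.values()) - tp

        planted_s = multiset(tuple(x) for x in truth.statuses.get(doc.doc_id, []))
        got_s = multiset(
            [("smoking", s) for s in doc.extracted.get("smoking_status_value", [])]
            + [("allergy", s) for s in doc.extracted.get("allergy_status_value", [])])
        for key in [k for kind, k in keys if kind == "status"]:
            p_n = planted_s.get(key, 0)
            g_n = got_s.get(key, 0)
            tp = min(p_n, g_n)
            counters[("status", key)]["tp"] += tp
            counters[("status", key)]["fp"] += g_n - tp
            counters[("status", key)]["fn"] += p_n - tp

    rows = []
    for (kind, key), c in counters.items():
        name = key if kind == "vital" else f"{key[0]}:{key[1]}"
        extracted = c["tp"] + c["fp"]
        planted = c["tp"] + c["fn"]
        rows.append({
            "field": name, "tp": c["tp"], "fp": c["fp"], "fn": c["fn"],
            "precision": c["tp"] / extracted if extracted else float("nan"),
            "recall": c["tp"] / planted if planted else float("nan"),
        })
    return pd.DataFrame(rows).set_index("field")


# ---------------------------------------------------------------- run dirs --
def write_run(config: SimConfig, out_dir: str | Path) -> Path:
    """Generate databases + corpus + truth + manifest under one directory."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dips, mv, db_truth = generate_databases(config, out_dir)
    docs, note_truth = generate_notes(config)
    corpus = out_dir / "notes.jsonl"
    write_corpus(docs, corpus)
    truth = GroundTruth(
        vitals=note_truth.vitals, statuses=note_truth.statuses,
        measurements=db_truth.measurements, encounters=db_truth.encounters)
    (out_dir / "ground_truth.json").write_text(
        json.dumps(truth.to_json(), ensure_ascii=False, sort_keys=True),
        encoding="utf-8")
    manifest = {
        "seed": config.seed,
        "config_sha256": config.sha256(),
        "package_version": __version__,
        "files": sorted(p.name for p in (dips, mv, corpus,
                                         out_dir / "ground_truth.json")),
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8")
    return out_dir
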