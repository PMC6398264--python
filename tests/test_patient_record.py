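"""Record fusion: merging, summaries, encounters, critical info, caching."""

import datetime as dt
import sqlite3

import pytest

from carefuse import ns
from carefuse.errors import PatientNotFoundError
from carefuse.extraction import VitalExtraction, annotate_corpus
from carefuse.mapping_engine import Triple, materialize, parse_mappings
from carefuse.patient_record import (
    Measurement,
    RecordAssembler,
    SourceRef,
    critical_info,
    list_encounters,
    merge_measurements,
    plan_summary,
    structured_measurements,
    summarize,
)
from carefuse.synthetic_data import (
    SimConfig,
    generate_databases,
    generate_notes,
    generate_status_profile_corpus,
)
from carefuse.text_index import DocumentRecord, build_index
from carefuse.triple_store import TripleStore
from carefuse.vocabulary import packaged_path


def meas(value, ts, system="DIPS", rid="m1", measure="weight"):
    return Measurement(measure, value, "kg", dt.datetime.fromisoformat(ts),
                       SourceRef(system, rid))


def vital(value, snippet="Vekt: 80 kg", measure="weight"):
    return VitalExtraction(measure=measure, value=value, unit="kg",
                           snippet=snippet, span=(0, len(snippet)))


def note(doc_id, ts, text="Vekt: 80 kg", extracted=None):
    d = DocumentRecord(doc_id, "1", "andre", ts, text)
    if extracted:
        d.extracted = extracted
    return d


class TestMerge:
    def test_structured_and_extracted_kept_side_by_side(self):
        structured = [meas(80.0, "2015-01-01T10:00:00", rid="m1"),
                      meas(82.0, "2015-02-01T10:00:00", system="Metavision",
                           rid="m2")]
        extracted = [(vital(80.0), note("d1", "2015-03-01T10:00:00"))]
        merged = merge_measurements(structured, extracted)
        series = merged.series["weight"]
        assert len(series) == 3
        systems = {m.provenance.system for m in series}
        assert systems == {"DIPS", "Metavision", "document"}
        doc_items = [m for m in series if m.provenance.system == "document"]
        assert doc_items[0].provenance.snippet == "Vekt: 80 kg"

    def test_no_deduplication_of_identical_values(self):
        structured = [meas(80.0, "2015-01-01T10:00:00", rid="m1"),
                      meas(80.0, "2015-01-01T10:00:00", system="Metavision",
                           rid="m2")]
        merged = merge_measurements(structured)
        assert len(merged.series["weight"]) == 2

    def test_empty_inputs_give_empty_map(self):
        merged = merge_measurements([], [])
        assert merged.series == {} and merged.quarantined == []

    def test_series_reverse_chronological(self):
        ts = ["2015-01-01T10:00:00", "2016-01-01T10:00:00",
              "2014-01-01T10:00:00"]
        merged = merge_measurements([meas(i, t, rid=f"m{i}")
                                     for i, t in enumerate(ts)])
        got = [m.timestamp.isoformat() for m in merged.series["weight"]]
        assert got == sorted(ts, reverse=True)

    def test_bad_timestamp_is_quarantined_and_counted(self, caplog):
        extracted = [(vital(80.0), note("d1", "not-a-date")),
                     (vital(81.0), note("d2", "2015-01-01T10:00:00"))]
        with caplog.at_level("WARNING"):
            merged = merge_measurements([], extracted)
        assert merged.total() == 1
        assert len(merged.quarantined) == 1
        assert merged.quarantined[0]["doc_id"] == "d1"

    def test_conservation(self):
        structured = [meas(float(i), f"2015-01-0{i}T10:00:00", rid=f"m{i}")
                      for i in range(1, 6)]
        extracted = [(vital(80.0), note("d1", "2015-02-01T10:00:00"))]
        merged = merge_measurements(structured, extracted)
        assert merged.total() + len(merged.quarantined) == 6


class TestSummarize:
    def test_min_max_and_latest(self):
        series = [meas(80.0, "2015-02-01T10:00:00"),
                  meas(72.0, "2015-01-01T10:00:00"),
                  meas(91.0, "2015-03-01T10:00:00")]
        s = summarize(series)
        assert (s.minimum, s.maximum, s.latest_value) == (72.0, 91.0, 91.0)

    def test_singleton_series(self):
        s = summarize([meas(70.0, "2015-01-01T10:00:00")])
        assert s.minimum == s.maximum == s.latest_value == 70.0

    def test_empty_series_gives_none(self):
        assert summarize([]) is None

    def test_timestamp_tie_prefers_larger_value(self):
        series = [meas(70.0, "2015-01-01T10:00:00", rid="a"),
                  meas(75.0, "2015-01-01T10:00:00", rid="b")]
        assert summarize(series).latest_value == 75.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_scan_oracle_on_random_series(self, seed):
        import random
        rng = random.Random(seed)
        series = [meas(float(rng.randrange(40, 200)),
                       f"201{rng.randrange(3, 7)}-0{rng.randrange(1, 9)}-0"
                       f"{rng.randrange(1, 9)}T10:00:00", rid=f"m{i}")
                  for i in range(20)]
        s = summarize(series)
        values = [m.value for m in series]
        assert s.minimum == min(values)
        assert s.maximum == max(values)
        latest_ts = max(m.timestamp for m in series)
        assert s.latest_value == max(m.value for m in series
                                     if m.timestamp == latest_ts)


@pytest.fixture(scope="module")
def graph_backend(registry, tmp_path_factory):
    out = tmp_path_factory.mktemp("fusion")
    dips, mv, truth = generate_databases(SimConfig(seed=30, n_patients=5), out)
    store = TripleStore()
    for path, name, system in ((dips, "mappings_dips.ttl", "DIPS"),
                               (mv, "mappings_metavision.ttl", "Metavision")):
        rules = parse_mappings(packaged_path(name), registry)
        store.add_all(materialize(rules, sqlite3.connect(path), system))
    return store, truth


class TestEncounters:
    def test_reverse_chronological_with_ongoing_flags(self, graph_backend,
                                                      registry):
        store, truth = graph_backend
        for pid, expected in truth.encounters.items():
            got = list_encounters(f"{ns.DATA}patient/{pid}", store, registry)
            assert len(got) == len(expected)
            starts = [e.start.isoformat() for e in got]
            assert starts == sorted(starts, reverse=True)
            by_id = {e["id"]: e for e in expected}
            for enc in got:
                enc_id = int(enc.iri.rsplit("/", 1)[1])
                assert enc.ongoing == (by_id[enc_id]["end"] is None)

    def test_diagnoses_resolve_to_disease_classes(self, graph_backend,
                                                  registry):
        store, truth = graph_backend
        resolved = 0
        for pid in truth.encounters:
            for enc in list_encounters(f"{ns.DATA}patient/{pid}", store,
                                       registry):
                for code, disease in enc.diagnoses:
                    if disease is not None:
                        assert disease.startswith(ns.OBO)
                        resolved += 1
        assert resolved > 0

    def test_unknown_patient_gives_empty_list(self, graph_backend, registry):
        store, _ = graph_backend
        assert list_encounters(f"{ns.DATA}patient/999", store, registry) == []


class TestStructuredMeasurements:
    def test_every_db_row_surfaces_with_system_provenance(self, graph_backend,
                                                          registry):
        store, truth = graph_backend
        for pid, rows in truth.measurements.items():
            got = structured_measurements(f"{ns.DATA}patient/{pid}", store,
                                          registry)
            assert len(got) == len(rows)
            expected = {(r["system"], r["type"], r["value"]) for r in rows}
            assert {(m.provenance.system, m.measure, m.value)
                    for m in got} == expected


class TestCriticalInfo:
    def test_seven_nine_one_smoking_breakdown(self, pack_no):
        docs = generate_status_profile_corpus(
            "1", {"negative": 7, "uncertain": 9, "former": 1})
        summary = critical_info(annotate_corpus(docs, pack_no))
        assert summary.counts("smoking") == {"negative": 7, "uncertain": 9,
                                             "former": 1}
        for status, entries in summary.smoking.items():
            assert len(entries) == summary.counts("smoking")[status]
            for e in entries:
                assert e.snippet and e.doc_id and e.timestamp

    def test_patient_without_notes_gives_empty_summary(self):
        summary = critical_info([])
        assert summary.smoking == {} and summary.allergy == {}


class TestAssembler:
    @pytest.fixture()
    def assembler(self, graph_backend, registry, pack_no):
        store, _ = graph_backend
        docs, _ = generate_notes(SimConfig(seed=30, n_patients=5,
                                           notes_per_patient=(3, 8)))
        index = build_index(annotate_corpus(docs, pack_no))
        return RecordAssembler(store, index, registry)

    def test_unknown_patient_raises_not_found(self, assembler):
        with pytest.raises(PatientNotFoundError):
            assembler.assemble("999")

    def test_cache_hit_on_repeated_assembly(self, assembler):
        first = assembler.assemble("1")
        count = assembler.query_count
        second = assembler.assemble("1")
        assert second is first
        assert assembler.query_count == count

    def test_backend_mutation_invalidates_cache(self, assembler):
        first = assembler.assemble("1")
        count = assembler.query_count
        assembler.store.add(Triple("http://x/new", ns.RDF_TYPE,
                                   ns.AHUS + "ClinicalDocument"))
        second = assembler.assemble("1")
        assert assembler.query_count == count + 1
        assert second is not first

    def test_record_equals_piecewise_assembly(self, assembler, registry):
        record = assembler.assemble("2")
        iri = assembler.patient_iri("2")
        encounters = list_encounters(iri, assembler.store, registry)
        assert [e.iri for e in record.encounters] == [e.iri for e in encounters]
        docs = [d for d in assembler.index.docs.values()
                if d.patient_id == "2"]
        assert record.critical.counts("smoking") == \
            critical_info(docs).counts("smoking")

    def test_provenance_totality(self, assembler):
        record = assembler.assemble("1")
        for series in record.measurements.series.values():
            for m in series:
                assert m.provenance.system in ("DIPS", "Metavision",
                                               "document")
                if m.provenance.system == "document":
                    assert m.provenance.snippet

    def test_plan_summary_bounds_and_counts(self, assembler):
        record = assembler.assemble("1")
        for measure, s in record.plan.measures.items():
            assert s.minimum <= s.maximum
            assert s.minimum <= s.latest_value <= s.maximum
            series = record.measurements.series[measure]
            assert len(s.values) == len(series)
        assert record.plan.smoking_counts == \
            record.critical.counts("smoking")

    def test_json_export_has_versioned_schema(self, assembler):
        payload = assembler.assemble("1").to_json()
        assert payload["schema_version"]
        assert set(payload) >= {"patient", "administrative", "encounters",
                                "measurements", "critical_information",
                                "plan_summary"}
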