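"""R2RML-subset parsing, IRI minting and materialization."""

import sqlite3

import pytest

from carefuse import ns
from carefuse.errors import (
    MappingValidationError,
    MaterializationError,
    MintingError,
)
from carefuse.mapping_engine import (
    Literal,
    Triple,
    export_ntriples,
    load_ntriples,
    materialize,
    mint_iri,
    normalize_literal,
    parse_mappings,
)
from carefuse.synthetic_data import SimConfig, generate_databases
from carefuse.vocabulary import packaged_path

MAPPING_HEADER = """\
@prefix rr: <http://www.w3.org/ns/r2rml#> .
@prefix ahus: <http://data.ahus.no/onto#> .
@prefix xsd: <http://www.w3.org/2001/XMLSchema#> .
"""


class TestMinting:
    def test_table_and_primary_key_template(self):
        got = mint_iri("http://data.ahus.no/rd/patient/{id}", {"id": 12345})
        assert got == "http://data.ahus.no/rd/patient/12345"

    def test_reserved_characters_are_percent_encoded(self):
        assert mint_iri("http://x/{v}", {"v": "a b"}) == "http://x/a%20b"
        assert mint_iri("http://x/{v}", {"v": "a/b"}) == "http://x/a%2Fb"

    def test_null_key_raises(self):
        with pytest.raises(MintingError):
            mint_iri("http://x/{id}", {"id": None})

    def test_deterministic(self):
        row = {"a": 1, "b": "x y"}
        t = "http://x/{a}/{b}"
        assert mint_iri(t, row) == mint_iri(t, row)


class TestParsing:
    def test_packaged_dips_mapping_parses(self, registry):
        rules = parse_mappings(packaged_path("mappings_dips.ttl"), registry)
        patient = [r for r in rules if r.subject_class == ns.PATIENT_CLASS
                   and r.logical_table == "patient"]
        assert len(patient) == 1
        assert any(m.predicate == ns.AHUS + "socialSecurityNumber"
                   for m in patient[0].predicate_object_maps)

    def test_file_without_triples_maps_gives_empty_list(self, registry,
                                                        tmp_path):
        path = tmp_path / "empty.ttl"
        path.write_text(MAPPING_HEADER)
        assert parse_mappings(path, registry) == []

    def test_unknown_property_is_rejected(self, registry, tmp_path):
        path = tmp_path / "bad.ttl"
        path.write_text(MAPPING_HEADER + """
<#M> rr:logicalTable [ rr:tableName "patient" ] ;
  rr:subjectMap [ rr:template "http://x/{id}" ; rr:class ahus:HospitalPatient ] ;
  rr:predicateObjectMap [ rr:predicate ahus:noSuchProperty ;
                          rr:objectMap [ rr:column "ssn" ] ] .
""")
        with pytest.raises(MappingValidationError):
            parse_mappings(path, registry)

    def test_unsupported_construct_is_named(self, registry, tmp_path):
        path = tmp_path / "graphmap.ttl"
        path.write_text(MAPPING_HEADER + """
<#M> rr:logicalTable [ rr:tableName "patient" ] ;
  rr:subjectMap [ rr:template "http://x/{id}" ;
                  rr:graphMap [ rr:constant <http://g> ] ] .
""")
        with pytest.raises(MappingValidationError) as err:
            parse_mappings(path, registry)
        assert "rr:graphMap" in str(err.value)


@pytest.fixture
def micro_mapping(registry, tmp_path):
    path = tmp_path / "micro.ttl"
    path.write_text(MAPPING_HEADER + """
<#Enc> rr:logicalTable [ rr:tableName "encounter" ] ;
  rr:subjectMap [ rr:template "http://data.ahus.no/rd/encounter/{id}" ;
                  rr:class ahus:HospitalEncounter ] ;
  rr:predicateObjectMap [ rr:predicate ahus:encounterTitle ;
                          rr:objectMap [ rr:column "title" ] ] ;
  rr:predicateObjectMap [ rr:predicate ahus:encounterStartDate ;
                          rr:objectMap [ rr:column "start_date" ; rr:datatype xsd:date ] ] ;
  rr:predicateObjectMap [ rr:predicate ahus:involvesPatient ;
                          rr:objectMap [ rr:template "http://data.ahus.no/rd/patient/{patient_id}" ] ] .
""")
    return parse_mappings(path, registry)


class TestMaterialize:
    def test_one_row_two_columns_one_fk_gives_four_triples(self, micro_mapping):
        conn = sqlite3.connect(":memory:")
        conn.execute("CREATE TABLE encounter(id, patient_id, title, start_date)")
        conn.execute("INSERT INTO encounter VALUES (1, 7, 'Kontroll', '2015-01-02')")
        triples = materialize(micro_mapping, conn, "DIPS")
        assert len(triples) == 4
        assert Triple("http://data.ahus.no/rd/encounter/1", ns.RDF_TYPE,
                      ns.AHUS + "HospitalEncounter", "DIPS") in triples

    def test_empty_table_gives_no_triples(self, micro_mapping):
        conn = sqlite3.connect(":memory:")
        conn.execute("CREATE TABLE encounter(id, patient_id, title, start_date)")
        assert materialize(micro_mapping, conn) == set()

    def test_null_columns_produce_no_triples(self, micro_mapping):
        conn = sqlite3.connect(":memory:")
        conn.execute("CREATE TABLE encounter(id, patient_id, title, start_date)")
        conn.execute("INSERT INTO encounter VALUES (1, NULL, NULL, '2015-01-02')")
        triples = materialize(micro_mapping, conn)
        assert len(triples) == 2  # type + start date only

    def test_null_subject_key_skips_row_with_warning(self, micro_mapping,
                                                     caplog):
        conn = sqlite3.connect(":memory:")
        conn.execute("CREATE TABLE encounter(id, patient_id, title, start_date)")
        conn.execute("INSERT INTO encounter VALUES (NULL, 1, 'x', '2015-01-02')")
        with caplog.at_level("WARNING"):
            assert materialize(micro_mapping, conn) == set()
        assert "skipped" in caplog.text

    def test_missing_table_is_reported_with_rule_name(self, micro_mapping):
        conn = sqlite3.connect(":memory:")
        with pytest.raises(MaterializationError) as err:
            materialize(micro_mapping, conn)
        assert "encounter" in str(err.value)


def _closed_form_count(conn: sqlite3.Connection, rules) -> int:
    """SQL aggregation oracle: rows x (type + non-null columns + non-null FKs)."""
    total = 0
    for rule in rules:
        src = rule.logical_table if rule.is_query \
            else f'SELECT * FROM "{rule.logical_table}"'
        terms = []
        if rule.subject_class:
            terms.append("1")
        for m in rule.predicate_object_maps:
            terms.append(f'(CASE WHEN "{m.column}" IS NULL THEN 0 ELSE 1 END)')
        for m in rule.ref_object_maps:
            terms.append(f'(CASE WHEN "{m.column}" IS NULL THEN 0 ELSE 1 END)')
        if not terms:
            continue
        total += conn.execute(
            f"SELECT COALESCE(SUM({' + '.join(terms)}), 0) FROM ({src})"
        ).fetchone()[0]
    return total


@pytest.fixture(scope="module")
def fixture_run(registry, tmp_path_factory):
    out = tmp_path_factory.mktemp("dbs")
    dips, mv, _ = generate_databases(SimConfig(seed=42, n_patients=10), out)
    rules_d = parse_mappings(packaged_path("mappings_dips.ttl"), registry)
    rules_m = parse_mappings(packaged_path("mappings_metavision.ttl"),
                             registry)
    return dips, mv, rules_d, rules_m


class TestOnSyntheticFixture:
    def test_triple_count_matches_sql_aggregation_oracle(self, fixture_run):
        dips, mv, rules_d, rules_m = fixture_run
        for db, rules, system in ((dips, rules_d, "DIPS"),
                                  (mv, rules_m, "Metavision")):
            conn = sqlite3.connect(db)
            triples = materialize(rules, conn, system)
            assert len(triples) == _closed_form_count(conn, rules)

    def test_materialization_is_deterministic(self, fixture_run):
        dips, _, rules_d, _ = fixture_run
        conn = sqlite3.connect(dips)
        assert materialize(rules_d, conn, "DIPS") == \
            materialize(rules_d, conn, "DIPS")

    def test_disjoint_sources_union_equals_single_pass(self, fixture_run):
        dips, mv, rules_d, rules_m = fixture_run
        a = materialize(rules_d, sqlite3.connect(dips), "DIPS")
        b = materialize(rules_m, sqlite3.connect(mv), "Metavision")
        union_then = a | b
        again = materialize(rules_d, sqlite3.connect(dips), "DIPS") | \
            materialize(rules_m, sqlite3.connect(mv), "Metavision")
        assert union_then == again

    def test_no_dangling_object_references(self, fixture_run):
        """Every FK-produced object IRI is minted as a subject somewhere."""
        dips, mv, rules_d, rules_m = fixture_run
        triples = materialize(rules_d, sqlite3.connect(dips), "DIPS") | \
            materialize(rules_m, sqlite3.connect(mv), "Metavision")
        subjects = {t.subject for t in triples}
        ref_props = {ns.AHUS + "involvesPatient", ns.AHUS + "hasEncounter",
                     ns.AHUS + "measurementOfPatient"}
        for t in triples:
            if t.predicate in ref_props:
                assert t.object in subjects

    def test_ntriples_round_trip(self, fixture_run, tmp_path):
        dips, _, rules_d, _ = fixture_run
        triples = materialize(rules_d, sqlite3.connect(dips), "DIPS")
        path = tmp_path / "graph.nt"
        export_ntriples(triples, path)
        back = load_ntriples(path, "DIPS")
        assert back == triples


class TestLiteralNormalization:
    @pytest.mark.parametrize("raw, datatype, expected", [
        ("02.03.2015", "date", "2015-03-02"),
        ("2015-03-02", "date", "2015-03-02"),
        ("2015-03-02 10:30", "dateTime", "2015-03-02T10:30:00"),
        (72, "integer", "72"),
        (72.5, "decimal", "72.5"),
        (72.0, "decimal", "72"),
    ])
    def test_values_are_canonicalized_to_iso(self, raw, datatype, expected):
        assert normalize_literal(raw, datatype) == Literal(expected, datatype)

    def test_unparseable_date_raises(self):
        with pytest.raises(ValueError):
            normalize_literal("someday", "date")
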