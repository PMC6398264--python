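"""Regenerate the packaged R2RML mapping files for the two source systems.

One Turtle file per simulated system (DIPS-role EHR, Metavision-role
physician order entry).  Patients share one IRI space across systems so
the materialized graphs unify; measurements are minted per system.

Run from the repository root:

    python scripts/generate_mappings.py
"""

from __future__ import annotations

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from carefuse import ns  # noqa: E402

DATA_DIR = Path(__file__).resolve().parents[1] / "src/carefuse/data"

HEADER = """\
@prefix rr:   <http://www.w3.org/ns/r2rml#> .
@prefix ahus: <http://data.ahus.no/onto#> .
@prefix obo:  <http://purl.obolibrary.org/obo/> .
@prefix foaf: <http://xmlns.com/foaf/0.1/> .
@prefix xsd:  <http://www.w3.org/2001/XMLSchema#> .
@prefix map:  <http://data.ahus.no/mappings/{system}#> .

"""

PATIENT_DIPS = """\
map:PatientMap a rr:TriplesMap ;
  rr:logicalTable [ rr:tableName "patient" ] ;
  rr:subjectMap [ rr:template "http://data.ahus.no/rd/patient/{id}" ;
                  rr:class ahus:HospitalPatient ] ;
  rr:predicateObjectMap [ rr:predicate ahus:socialSecurityNumber ;
                          rr:objectMap [ rr:column "ssn" ] ] ;
  rr:predicateObjectMap [ rr:predicate foaf:name ;
                          rr:objectMap [ rr:column "name" ] ] ;
  rr:predicateObjectMap [ rr:predicate ahus:dateOfBirth ;
                          rr:objectMap [ rr:column "birth_date" ; rr:datatype xsd:date ] ] ;
  rr:predicateObjectMap [ rr:predicate foaf:gender ;
                          rr:objectMap [ rr:column "gender" ] ] .

map:EncounterMap a rr:TriplesMap ;
  rr:logicalTable [ rr:tableName "encounter" ] ;
  rr:subjectMap [ rr:template "http://data.ahus.no/rd/encounter/{id}" ;
                  rr:class ahus:HospitalEncounter ] ;
  rr:predicateObjectMap [ rr:predicate ahus:encounterStartDate ;
                          rr:objectMap [ rr:column "start_date" ; rr:datatype xsd:date ] ] ;
  rr:predicateObjectMap [ rr:predicate ahus:encounterEndDate ;
                          rr:objectMap [ rr:column "end_date" ; rr:datatype xsd:date ] ] ;
  rr:predicateObjectMap [ rr:predicate ahus:encounterTitle ;
                          rr:objectMap [ rr:column "title" ] ] ;
  rr:predicateObjectMap [ rr:predicate ahus:icd10Code ;
                          rr:objectMap [ rr:column "icd10_code" ] ] ;
  rr:predicateObjectMap [ rr:predicate ahus:operationCode ;
                          rr:objectMap [ rr:column "operation_code" ] ] ;
  rr:predicateObjectMap [ rr:predicate ahus:involvesPatient ;
                          rr:objectMap [ rr:template "http://data.ahus.no/rd/patient/{patient_id}" ] ] .

map:PatientEncounterLinkMap a rr:TriplesMap ;
  rr:logicalTable [ rr:tableName "encounter" ] ;
  rr:subjectMap [ rr:template "http://data.ahus.no/rd/patient/{patient_id}" ] ;
  rr:predicateObjectMap [ rr:predicate ahus:hasEncounter ;
                          rr:objectMap [ rr:template "http://data.ahus.no/rd/encounter/{id}" ] ] .

"""

PATIENT_MV = """\
map:PatientMap a rr:TriplesMap ;
  rr:logicalTable [ rr:tableName "patient" ] ;
  rr:subjectMap [ rr:template "http://data.ahus.no/rd/patient/{id}" ;
                  rr:class ahus:HospitalPatient ] ;
  rr:predicateObjectMap [ rr:predicate foaf:name ;
                          rr:objectMap [ rr:column "name" ] ] ;
  rr:predicateObjectMap [ rr:predicate ahus:dateOfBirth ;
                          rr:objectMap [ rr:column "birth_date" ; rr:datatype xsd:date ] ] .

"""

MEASUREMENT = """\
map:{title}MeasurementMap a rr:TriplesMap ;
  rr:logicalTable [ rr:sqlQuery "SELECT * FROM measurement WHERE type = '{measure}'" ] ;
  rr:subjectMap [ rr:template "http://data.ahus.no/rd/{table}/{{id}}" ;
                  rr:class {cls} ] ;
  rr:predicateObjectMap [ rr:predicate ahus:measurementValue ;
                          rr:objectMap [ rr:column "value" ; rr:datatype xsd:decimal ] ] ;
  rr:predicateObjectMap [ rr:predicate ahus:measurementUnit ;
                          rr:objectMap [ rr:column "unit" ] ] ;
  rr:predicateObjectMap [ rr:predicate ahus:measurementTimestamp ;
                          rr:objectMap [ rr:column "ts" ; rr:datatype xsd:dateTime ] ] ;
  rr:predicateObjectMap [ rr:predicate ahus:measurementOfPatient ;
                          rr:objectMap [ rr:template "http://data.ahus.no/rd/patient/{{patient_id}}" ] ] .

map:{title}LinkMap a rr:TriplesMap ;
  rr:logicalTable [ rr:sqlQuery "SELECT * FROM measurement WHERE type = '{measure}'" ] ;
  rr:subjectMap [ rr:template "http://data.ahus.no/rd/patient/{{patient_id}}" ] ;
  rr:predicateObjectMap [ rr:predicate <{link}> ;
                          rr:objectMap [ rr:template "http://data.ahus.no/rd/{table}/{{id}}" ] ] .

"""


def curie(iri: str) -> str:
    if iri.startswith(ns.AHUS):
        return "ahus:" + iri[len(ns.AHUS):]
    if iri.startswith(ns.OBO):
        return "obo:" + iri[len(ns.OBO):]
    return f"<{iri}>"


def build(system: str, patient_block: str, meas_table: str) -> str:
    parts = [HEADER.format(system=system), patient_block]
    for measure, (cls, link, _unit) in ns.MEASURE_TYPES.items():
        title = "".join(w.capitalize() for w in measure.split("_"))
        parts.append(MEASUREMENT.format(
            title=title, measure=measure, table=meas_table,
            cls=curie(cls), link=link))
    return "".join(parts)


def main() -> int:
    (DATA_DIR / "mappings_dips.ttl").write_text(
        build("dips", PATIENT_DIPS, "dips_measurement"), encoding="utf-8")
    (DATA_DIR / "mappings_metavision.ttl").write_text(
        build("metavision", PATIENT_MV, "mv_measurement"), encoding="utf-8")
    print("wrote mappings_dips.ttl and mappings_metavision.ttl")
    return 0


if __name__ == "__main__":
    sys.exit(main())
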