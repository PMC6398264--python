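"""Namespace constants shared across the package.

Local terms live in a single artifact namespace (``AHUS``); everything
else (OBO Foundry fragments, FOAF, PAV) is treated as imported.
Entity IRIs for relational individuals are minted under ``DATA``.
"""

AHUS = "http://data.ahus.no/onto#"
DATA = "http://data.ahus.no/rd/"
OBO = "http://purl.obolibrary.org/obo/"
FOAF = "http://xmlns.com/foaf/0.1/"
PAV = "http://purl.org/pav/"

RDF_TYPE = "http://www.w3.org/1999/02/22-rdf-syntax-ns#type"
RDFS_LABEL = "http://www.w3.org/2000/01/rdf-schema#label"
RDFS_SUBCLASSOF = "http://www.w3.org/2000/01/rdf-schema#subClassOf"
RDFS_SUBPROPERTYOF = "http://www.w3.org/2000/01/rdf-schema#subPropertyOf"
XSD = "http://www.w3.org/2001/XMLSchema#"

# Upper-level anchors of the patient-care ontology.
PATIENT_CLASS = AHUS + "HospitalPatient"
DISEASE_ROOT = OBO + "OGMS_0000031"          # disease
ENCOUNTER_ROOT = OBO + "OGMS_0000097"        # health care encounter
DATA_ITEM_ROOT = OBO + "IAO_0000027"         # data item
SCALAR_MEASUREMENT_ROOT = OBO + "IAO_0000032"  # scalar measurement datum
INTESTINAL_DISEASE = OBO + "DOID_5295"

# The seven pilot vital-sign measures plus the ASA illness severity score.
# measure key -> (ontology class, patient-link object property, canonical unit)
MEASURE_TYPES = {
    "pulse": (OBO + "CMO_0000002", AHUS + "personPulseMeasurement", "bpm"),
    "temperature": (OBO + "CMO_0000015", AHUS + "personTemperatureMeasurement", "C"),
    "systolic_bp": (OBO + "CMO_0000004",
                    AHUS + "personSystolicBloodPressureMeasurement", "mmHg"),
    "diastolic_bp": (OBO + "CMO_0000005",
                     AHUS + "personDiastolicBloodPressureMeasurement", "mmHg"),
    "weight": (OBO + "CMO_0000012", AHUS + "personWeightMeasurement", "kg"),
    "height": (OBO + "CMO_0000106", AHUS + "personHeightMeasurement", "cm"),
    "bmi": (OBO + "CMO_0000105", AHUS + "personBmiMeasurement", "kg/m2"),
    "asa": (AHUS + "IllnessSeverityScore",
            AHUS + "personIllnessSeverityScore", "ASA"),
}

#: XSD datatypes permitted for typed literals in the materialized graph.
LITERAL_DATATYPES = {
    "string": XSD + "string",
    "integer": XSD + "integer",
    "decimal": XSD + "decimal",
    "dateTime": XSD + "dateTime",
    "date": XSD + "date",
}
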