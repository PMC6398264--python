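"""Regenerate the packaged patient-care ontology and ICD-10 cross-reference table.

This script is the authoritative roster of the ontology: 84 local classes,
36 local object properties, 12 local datatype properties and 13 local
annotation properties in the artifact namespace, plus a curated imported
fragment (upper-level anchors, a Disease Ontology subtree with ICD-10
cross-references, clinical measurement subtypes, FOAF and PAV terms).

Run from the repository root:

    python scripts/generate_ontology.py
"""

from __future__ import annotations

import sys
from pathlib import Path

from rdflib import Graph, Literal, Namespace, RDF, RDFS, OWL, URIRef

AHUS = Namespace("http://data.ahus.no/onto#")
OBO = Namespace("http://purl.obolibrary.org/obo/")
FOAF = Namespace("http://xmlns.com/foaf/0.1/")
PAV = Namespace("http://purl.org/pav/")

OUT_TTL = Path(__file__).resolve().parents[1] / "src/carefuse/data/ontology.ttl"
OUT_XREF = Path(__file__).resolve().parents[1] / "src/carefuse/data/icd10_xref.tsv"


def camel_label(name: str) -> str:
    out = []
    for i, ch in enumerate(name):
        if ch.isupper() and i > 0 and not name[i - 1].isupper():
            out.append(" ")
        out.append(ch.lower())
    return "".join(out)


# ---------------------------------------------------------------- imported --
# (iri-suffix-or-full, label, parent or None)
IMPORTED_CLASSES = [
    (OBO.NCBITaxon_9606, "Homo sapiens", None),
    (OBO.BFO_0000023, "role", None),
    (OBO.OMRSE_00000011, "patient role", OBO.BFO_0000023),
    (OBO.OGMS_0000031, "disease", None),
    (OBO.OGMS_0000097, "health care encounter", None),
    (OBO.IAO_0000027, "data item", None),
    (OBO.IAO_0000032, "scalar measurement datum", OBO.IAO_0000027),
    (OBO.IAO_0000310, "document", OBO.IAO_0000027),
    (FOAF.Organization, "organization", None),
    # Clinical measurement subtypes reused for the seven pilot vital signs.
    (OBO.CMO_0000002, "heart rate measurement", OBO.IAO_0000032),
    (OBO.CMO_0000015, "body temperature measurement", OBO.IAO_0000032),
    (OBO.CMO_0000004, "systolic blood pressure measurement", OBO.IAO_0000032),
    (OBO.CMO_0000005, "diastolic blood pressure measurement", OBO.IAO_0000032),
    (OBO.CMO_0000012, "body weight measurement", OBO.IAO_0000032),
    (OBO.CMO_0000106, "body height measurement", OBO.IAO_0000032),
    (OBO.CMO_0000105, "body mass index measurement", OBO.IAO_0000032),
]

# Curated Disease Ontology fragment; top concept is the OGMS disease class.
DO_FRAGMENT = [
    (OBO.DOID_4, "disease", OBO.OGMS_0000031),
    (OBO.DOID_77, "gastrointestinal system disease", OBO.DOID_4),
    (OBO.DOID_5295, "intestinal disease", OBO.DOID_77),
    (OBO.DOID_8337, "appendicitis", OBO.DOID_5295),
    (OBO.DOID_8577, "ulcerative colitis", OBO.DOID_5295),
    (OBO.DOID_8778, "Crohn's disease", OBO.DOID_5295),
    (OBO.DOID_9778, "irritable bowel syndrome", OBO.DOID_5295),
    (OBO.DOID_13250, "diverticulitis", OBO.DOID_5295),
    (OBO.DOID_10608, "celiac disease", OBO.DOID_5295),
    (OBO.DOID_8437, "intestinal obstruction", OBO.DOID_5295),
    (OBO.DOID_0060180, "colitis", OBO.DOID_5295),
    (OBO.DOID_8534, "gastroesophageal reflux disease", OBO.DOID_77),
    (OBO.DOID_10763, "hypertension", OBO.DOID_4),
    (OBO.DOID_2841, "asthma", OBO.DOID_4),
    (OBO.DOID_9352, "type 2 diabetes mellitus", OBO.DOID_4),
    (OBO.DOID_3083, "chronic obstructive pulmonary disease", OBO.DOID_4),
    (OBO.DOID_552, "pneumonia", OBO.DOID_4),
    (OBO.DOID_13148, "urinary tract infection", OBO.DOID_4),
    (OBO.DOID_8398, "osteoarthritis", OBO.DOID_4),
    (OBO.DOID_0060224, "atrial fibrillation", OBO.DOID_4),
    (OBO.DOID_3393, "coronary artery disease", OBO.DOID_4),
    (OBO.DOID_1459, "hypothyroidism", OBO.DOID_4),
    (OBO.DOID_2355, "anemia", OBO.DOID_4),
    (OBO.DOID_9810, "cholelithiasis", OBO.DOID_77),
]

IMPORTED_OBJECT_PROPERTIES = [
    (OBO.RO_0000091, "has disposition"),
    (PAV.retrievedFrom, "retrieved from"),
    (PAV.importedFrom, "imported from"),
    (PAV.derivedFrom, "derived from"),
    (FOAF.img, "image"),
]

IMPORTED_DATATYPE_PROPERTIES = [
    (FOAF.name, "name"),
    (FOAF.gender, "gender"),
]

# ------------------------------------------------------------------- local --
# 8 administrative / organisational classes
ADMIN = [
    ("HospitalPatient", OBO.NCBITaxon_9606),
    ("ElectronicPatientRecord", OBO.IAO_0000027),
    ("AdministrativeDataItem", OBO.IAO_0000027),
    ("HospitalDepartment", FOAF.Organization),
    ("DaySurgeryUnit", "HospitalDepartment"),
    ("SurgicalTeam", FOAF.Organization),
    ("HealthcareProviderRole", OBO.BFO_0000023),
    ("AnesthesiologistRole", "HealthcareProviderRole"),
]

# 12 document-type classes (taxonomy of clinical note types)
DOCUMENTS = [
    ("ClinicalDocument", OBO.IAO_0000310),
    ("AdmissionDocument", "ClinicalDocument"),
    ("DischargeSummary", "ClinicalDocument"),
    ("OperationNote", "ClinicalDocument"),
    ("OutpatientNote", "ClinicalDocument"),
    ("NursingNote", "ClinicalDocument"),
    ("AnesthesiaNote", "ClinicalDocument"),
    ("ReferralLetter", "ClinicalDocument"),
    ("ProgressNote", "ClinicalDocument"),
    ("ConsultationNote", "ClinicalDocument"),
    ("RadiologyReport", "ClinicalDocument"),
    ("OtherDocument", "ClinicalDocument"),
]

# 10 encounter-type classes
ENCOUNTERS = [
    ("HospitalEncounter", OBO.OGMS_0000097),
    ("InpatientStay", "HospitalEncounter"),
    ("OutpatientVisit", "HospitalEncounter"),
    ("DaySurgeryEncounter", "HospitalEncounter"),
    ("EmergencyVisit", "HospitalEncounter"),
    ("PreoperativeAssessment", "HospitalEncounter"),
    ("PostoperativeFollowUp", "HospitalEncounter"),
    ("AnesthesiaEncounter", "HospitalEncounter"),
    ("ConsultationEncounter", "HospitalEncounter"),
    ("TelephoneConsultation", "ConsultationEncounter"),
]

# 16 operation classes following the NCSP chapter structure
OPERATIONS = [
    ("SurgicalOperation", OBO.OGMS_0000097),
    ("NervousSystemOperation", "SurgicalOperation"),
    ("EndocrineSystemOperation", "SurgicalOperation"),
    ("EyeOperation", "SurgicalOperation"),
    ("EarNoseThroatOperation", "SurgicalOperation"),
    ("DentalJawOperation", "SurgicalOperation"),
    ("HeartMajorVesselOperation", "SurgicalOperation"),
    ("ChestWallPleuraLungOperation", "SurgicalOperation"),
    ("BreastOperation", "SurgicalOperation"),
    ("DigestiveSystemOperation", "SurgicalOperation"),
    ("UrinarySystemOperation", "SurgicalOperation"),
    ("FemaleGenitalOperation", "SurgicalOperation"),
    ("ObstetricOperation", "SurgicalOperation"),
    ("MusculoskeletalOperation", "SurgicalOperation"),
    ("PeripheralVesselLymphOperation", "SurgicalOperation"),
    ("SkinOperation", "SurgicalOperation"),
]

# 4 measurement classes (local additions under scalar measurement datum)
MEASUREMENTS = [
    ("VitalSignMeasurementDatum", OBO.IAO_0000032),
    ("IllnessSeverityScore", "VitalSignMeasurementDatum"),  # ASA class
    ("BloodPressurePanel", "VitalSignMeasurementDatum"),
    ("DocumentExtractedMeasurementDatum", OBO.IAO_0000032),
]

# 10 critical-information status classes
STATUSES = [
    ("CriticalInformationItem", OBO.IAO_0000027),
    ("SmokingStatusDatum", "CriticalInformationItem"),
    ("CurrentSmokerStatus", "SmokingStatusDatum"),
    ("NonSmokerStatus", "SmokingStatusDatum"),
    ("ExSmokerStatus", "SmokingStatusDatum"),
    ("UncertainSmokerStatus", "SmokingStatusDatum"),
    ("AllergyStatusDatum", "CriticalInformationItem"),
    ("PositiveAllergyStatus", "AllergyStatusDatum"),
    ("NegativeAllergyStatus", "AllergyStatusDatum"),
    ("UncertainAllergyStatus", "AllergyStatusDatum"),
]

# 6 surgery-plan classes
PLAN = [
    ("OperationSurgeryPlan", OBO.IAO_0000310),
    ("SurgeonPlanSection", OBO.IAO_0000310),
    ("AnesthesiaPlanSection", OBO.IAO_0000310),
    ("ResourcePlanSection", OBO.IAO_0000310),
    ("PlanMeasurementSummary", OBO.IAO_0000027),
    ("PlanAllergySummary", OBO.IAO_0000027),
]

# 18 pre-operative risk condition placeholders under the disease root
CONDITIONS = [
    ("PreoperativeRiskCondition", OBO.OGMS_0000031),
    ("SleepApneaRiskCondition", "PreoperativeRiskCondition"),
    ("DifficultAirwayCondition", "PreoperativeRiskCondition"),
    ("MalignantHyperthermiaRisk", "PreoperativeRiskCondition"),
    ("ChronicAnticoagulationCondition", "PreoperativeRiskCondition"),
    ("LatexSensitivityCondition", "PreoperativeRiskCondition"),
    ("PostoperativeNauseaRisk", "PreoperativeRiskCondition"),
    ("AspirationRiskCondition", "PreoperativeRiskCondition"),
    ("CardiovascularRiskCondition", "PreoperativeRiskCondition"),
    ("RespiratoryRiskCondition", "PreoperativeRiskCondition"),
    ("MetabolicRiskCondition", "PreoperativeRiskCondition"),
    ("BleedingDisorderCondition", "PreoperativeRiskCondition"),
    ("ImmunosuppressionCondition", "PreoperativeRiskCondition"),
    ("ChronicPainCondition", "PreoperativeRiskCondition"),
    ("SubstanceDependenceCondition", "PreoperativeRiskCondition"),
    ("PregnancyRelatedRiskCondition", "PreoperativeRiskCondition"),
    ("FrailtyCondition", "PreoperativeRiskCondition"),
    ("UncodedDiseaseCondition", OBO.OGMS_0000031),
]

LOCAL_CLASSES = (
    ADMIN + DOCUMENTS + ENCOUNTERS + OPERATIONS + MEASUREMENTS + STATUSES + PLAN + CONDITIONS
)

# 36 local object properties; (name, parent or None)
LOCAL_OBJECT_PROPERTIES = [
    ("hasPatientRole", None),
    ("hasDisease", OBO.RO_0000091),
    ("hasDiagnosis", None),
    ("hasDiagnosedDisease", None),
    ("involvesPatient", None),
    ("hasEncounter", None),
    ("partOfEncounter", None),
    ("hasMeasurement", None),
    ("measurementOfPatient", None),
    ("hasDocument", None),
    ("documentAboutPatient", None),
    ("documentOfEncounter", None),
    ("hasOperation", None),
    ("performedDuringEncounter", None),
    ("hasOperationPlan", None),
    ("planForPatient", None),
    ("planHasSection", None),
    ("summarizesMeasurement", None),
    ("hasSmokingStatus", None),
    ("hasAllergyStatus", None),
    ("hasAllergen", None),
    ("assessmentFromDocument", None),
    ("hasCriticalInformation", None),
    ("recordedInSystem", None),
    ("retrievedFromSource", PAV.retrievedFrom),
    ("importedFromSystem", PAV.importedFrom),
    ("admittedToDepartment", None),
    ("treatedByTeam", None),
    ("personPulseMeasurement", "hasMeasurement"),
    ("personTemperatureMeasurement", "hasMeasurement"),
    ("personSystolicBloodPressureMeasurement", "hasMeasurement"),
    ("personDiastolicBloodPressureMeasurement", "hasMeasurement"),
    ("personWeightMeasurement", "hasMeasurement"),
    ("personHeightMeasurement", "hasMeasurement"),
    ("personBmiMeasurement", "hasMeasurement"),
    ("personIllnessSeverityScore", "hasMeasurement"),
]

# 12 local datatype properties
LOCAL_DATATYPE_PROPERTIES = [
    "socialSecurityNumber",
    "dateOfBirth",
    "encounterStartDate",
    "encounterEndDate",
    "encounterTitle",
    "icd10Code",
    "operationCode",
    "measurementValue",
    "measurementUnit",
    "measurementTimestamp",
    "documentTimestamp",
    "documentTypeCode",
]

# 13 local annotation properties
LOCAL_ANNOTATION_PROPERTIES = [
    "norwegianLabel",
    "abbreviation",
    "displayOrder",
    "uiColorHint",
    "sourceSystemNote",
    "extractionPatternId",
    "snippetText",
    "termStatus",
    "editorNote",
    "curatedBy",
    "versionNote",
    "exampleUsage",
    "definitionSource",
]

# ICD-10 code -> Disease Ontology cross-references (code maps to one class)
ICD10_XREFS = [
    ("K35", OBO.DOID_8337),
    ("K50", OBO.DOID_8778),
    ("K51", OBO.DOID_8577),
    ("K52", OBO.DOID_0060180),
    ("K56", OBO.DOID_8437),
    ("K57", OBO.DOID_13250),
    ("K58", OBO.DOID_9778),
    ("K90.0", OBO.DOID_10608),
    ("K21", OBO.DOID_8534),
    ("K80", OBO.DOID_9810),
    ("I10", OBO.DOID_10763),
    ("J45", OBO.DOID_2841),
    ("E11", OBO.DOID_9352),
    ("J44", OBO.DOID_3083),
    ("J18", OBO.DOID_552),
    ("N39.0", OBO.DOID_13148),
    ("M19", OBO.DOID_8398),
    ("I48", OBO.DOID_0060224),
    ("I25", OBO.DOID_3393),
    ("E03", OBO.DOID_1459),
    ("D64", OBO.DOID_2355),
]


def resolve(parent):
    if parent is None:
        return None
    if isinstance(parent, URIRef):
        return parent
    return AHUS[parent]


def main() -> int:
    assert len(LOCAL_CLASSES) == 84, len(LOCAL_CLASSES)
    assert len(LOCAL_OBJECT_PROPERTIES) == 36, len(LOCAL_OBJECT_PROPERTIES)
    assert len(LOCAL_DATATYPE_PROPERTIES) == 12
    assert len(LOCAL_ANNOTATION_PROPERTIES) == 13
    assert len({n for n, _ in LOCAL_CLASSES}) == 84
    assert len({n for n, _ in LOCAL_OBJECT_PROPERTIES}) == 36

    g = Graph()
    g.bind("ahus", AHUS)
    g.bind("obo", OBO)
    g.bind("foaf", FOAF)
    g.bind("pav", PAV)
    g.bind("owl", OWL)

    onto = URIRef("http://data.ahus.no/onto")
    g.add((onto, RDF.type, OWL.Ontology))
    g.add((onto, RDFS.label, Literal("Patient-care integration ontology")))

    for iri, label, parent in IMPORTED_CLASSES + DO_FRAGMENT:
        g.add((iri, RDF.type, OWL.Class))
        g.add((iri, RDFS.label, Literal(label)))
        if parent is not None:
            g.add((iri, RDFS.subClassOf, parent))

    for iri, label in IMPORTED_OBJECT_PROPERTIES:
        g.add((iri, RDF.type, OWL.ObjectProperty))
        g.add((iri, RDFS.label, Literal(label)))
    for iri, label in IMPORTED_DATATYPE_PROPERTIES:
        g.add((iri, RDF.type, OWL.DatatypeProperty))
        g.add((iri, RDFS.label, Literal(label)))

    for name, parent in LOCAL_CLASSES:
        iri = AHUS[name]
        g.add((iri, RDF.type, OWL.Class))
        g.add((iri, RDFS.label, Literal(camel_label(name))))
        g.add((iri, RDFS.subClassOf, resolve(parent)))

    for name, parent in LOCAL_OBJECT_PROPERTIES:
        iri = AHUS[name]
        g.add((iri, RDF.type, OWL.ObjectProperty))
        g.add((iri, RDFS.label, Literal(camel_label(name))))
        p = resolve(parent)
        if p is not None:
            g.add((iri, RDFS.subPropertyOf, p))

    for name in LOCAL_DATATYPE_PROPERTIES:
        iri = AHUS[name]
        g.add((iri, RDF.type, OWL.DatatypeProperty))
        g.add((iri, RDFS.label, Literal(camel_label(name))))

    for name in LOCAL_ANNOTATION_PROPERTIES:
        iri = AHUS[name]
        g.add((iri, RDF.type, OWL.AnnotationProperty))
        g.add((iri, RDFS.label, Literal(camel_label(name))))

    OUT_TTL.write_text(g.serialize(format="turtle"), encoding="utf-8")

    lines = ["\t".join(pair) for pair in sorted((c, str(i)) for c, i in ICD10_XREFS)]
    OUT_XREF.write_text("\n".join(lines) + "\n", encoding="utf-8")
    print(f"wrote {OUT_TTL} ({len(g)} triples) and {OUT_XREF} ({len(lines)} xrefs)")
    return 0


if __name__ == "__main__":
    sys.exit(main())
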