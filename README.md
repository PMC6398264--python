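# carefuse

Hybrid semantic and text-based integration of hospital patient data for
surgery planning.

Before an operation, the information a surgical team needs is scattered
across systems that do not talk to each other: an electronic health
record holding administrative data, ICD-10-tagged encounters and
vital-sign rows; a physician-order-entry system holding more
administrative and vital-sign rows; and an archive of free-text
clinical notes that, in many installations, cannot even be searched.
`carefuse` implements the back end of a pre-surgery reporting system
for this setting:

* **Ontology-based data access.** A patient-care ontology (built on
  OBO Foundry anchors: disease, health care encounter, data item,
  scalar measurement datum, plus a curated Disease Ontology fragment
  with ICD-10 cross-references) is connected to the two relational
  sources by declarative R2RML-subset mappings.  Entity IRIs are minted
  as `http://data.ahus.no/rd/{table_name}/{primary_key}`.  Instead of
  rewriting queries against the live databases, the engine materializes
  each source into an in-memory triple store that answers the four
  generic graph-query shapes a record browser needs (list patients,
  types of an individual, predicate–object list, subject–predicate
  list) plus conjunctive basic-graph-pattern queries with OWL 2 QL-style
  subclass/subproperty inference, e.g.

  ```sparql
  SELECT ?name WHERE {
    ?p ahus:hasDisease ?d .
    ?d a obo:DOID_5295 .        # intestinal disease — any subclass matches
    ?p foaf:name ?name
  }
  ```

* **Norwegian full-text search.** An embedded inverted index over the
  note corpus with the standard analysis chain (tokenization, case
  folding, stopword removal, snowball-style Norwegian stemming),
  boolean/phrase/fuzzy queries, metadata filters, and BM25 ranking
  damped by an exponential freshness factor (configurable half-life).

* **Rule-based clinical information extraction.** Editable YAML pattern
  packs extract the seven pilot vital signs (pulse, blood pressure,
  temperature, weight, height, BMI, ASA illness-severity score) with
  synonym/abbreviation support, decimal-comma normalization and
  plausibility ranges, and classify smoking status
  (positive/negative/former/uncertain) and allergy status
  (positive/negative/uncertain) with negation and question/
  recommendation handling.  Every extracted value is paired with the
  verbatim source snippet (`blood_pulse_value` / `blood_pulse_info`).

* **Provenance-tracked record fusion.** Per-patient views merge both
  structured systems and the notes into reverse-chronological
  measurement series, encounter lists with ongoing flags and
  ICD-10→disease resolution, critical-information summaries and a
  surgery-plan summary (latest/min/max per measure) — every datum
  carrying a `SourceRef` naming its system or document.

* **Synthetic study substrate.** Because real patient data is private,
  a seeded generator emulates both databases and a labeled
  Norwegian-style note corpus with known planted values, making every
  component testable end to end.

## Worked example

```bash
carefuse simulate --seed 1 --out run/
carefuse build --run run/
carefuse search "blod OR bt" --run run/ --doc-type andre
carefuse patient 1 --run run/ --view plan
```

Or from Python (see `examples/` for one script per capability):

```bash
python examples/05_patient_record.py
```

prints, for the seeded 10-patient fixture:

```
patient: Arne Nordmann (born 1968-07-22)
encounters: 6 (ongoing: 0)
  asa           latest    2.0 min    2.0 max    4.0 sources=['DIPS', 'Metavision']
  diastolic_bp  latest   89.0 min   55.0 max   98.0 sources=['DIPS', 'Metavision', 'document']
  pulse         latest   98.0 min   57.0 max   98.0 sources=['DIPS', 'Metavision', 'document']
  ...
smoking assessments: {'negative': 1, 'uncertain': 1}
```

Each line is one vital-sign series fused from up to three sources; the
`sources` list shows where the data points came from, and each point
keeps its own provenance (for document-sourced values, the exact text
snippet).  The smoking/allergy counts are per-status document counts
from the note-mining step.  `examples/03_search_notes.py` re-stages a
keyword search for `blod OR bt` over documents of type `andre` on a
corpus seeded with exactly 36 matching notes and reports `36 documents
found`.

## Query syntax

Terms are analyzed like documents.  `AND`/`OR`/`NOT` (adjacency binds
as AND), quoted `"phrases"`, trailing `term~1` / `term~2` for fuzzy
matching, parentheses for grouping.  Filters: patient, document type,
date range.  Results are paginated (default page size 10).

## Scope

This package is the data back end only: no web GUI, no
authentication, no synchronous plan editing, and no laboratory-test /
medication / imaging sources.  See `docs/methods.md` for the model,
parameter and design documentation.
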