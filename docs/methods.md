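# Methods

This note documents the models, parameters and design decisions behind
`carefuse`, and what the synthetic test substrate does and does not
show about real clinical data.

## The integration model

Two relational sources are integrated through a patient-care ontology
and declarative mappings. The ontology reuses upper-level anchors from
OBO Foundry ontologies — disease (OGMS) as the root of a curated
Disease Ontology fragment, health care encounter (OGMS), data item and
scalar measurement datum (IAO), clinical measurement subtypes (CMO) for
the vital signs — plus FOAF properties for basic personal data and PAV
properties for provenance. Local terms live in a single artifact
namespace: 84 classes (document types, encounter and operation types,
measurement subtypes including the ASA illness-severity score,
critical-information statuses, surgery-plan concepts, pre-operative
risk placeholders), 36 object properties, 12 datatype properties and
13 annotation properties. The roster is generated by
`scripts/generate_ontology.py`, which is the ontology's versioned
manifest; the identities of the local terms are this package's own
reconstruction of a plausible pilot vocabulary — the composition
counts are fixed, the names are editorial.

ICD-10 cross-references ship as a separate two-column table
(`data/icd10_xref.tsv`); each code maps to at most one disease class.
Only the OWL 2 QL constructs the package relies on are modelled:
class/property hierarchies with acyclicity validation. There is no
description-logic reasoning.

### Mappings and materialization

Mappings use the R2RML vocabulary restricted to: logical tables (table
name or embedded SQL select), template subject maps with an optional
class, column object maps with XSD datatypes, and template referencing
object maps for foreign keys. Graph maps, inverse expressions, parent
triples maps and constant object maps are rejected by name. Subject
classes are optional (as in R2RML itself) so that "link" rules — which
assert per-measure properties such as `ahus:personWeightMeasurement`
from the patient to each measurement individual — do not re-assert the
patient's type; with that convention the number of distinct triples
equals a closed form computable by SQL aggregation (rows × (type +
non-null mapped columns + non-null foreign keys)), which the tests use
as an independent oracle.

The original architecture answered queries by rewriting them against
the live databases; at desk scale this package materializes instead:
each source is translated once into an in-memory triple set whose
elements carry the source-system identifier. The observable query
contract is preserved by performing inference at query time (class and
property constants expand over the registry closure), which mirrors
rewriting semantics and keeps the store free of derived triples.
Patients are minted into one shared IRI space
(`…/rd/patient/{id}`) from both systems, so the graphs unify without
identity reasoning; measurements are minted per system. Date and
datetime literals are normalized to ISO-8601 on ingest regardless of
the source column format. Rows with a null subject key are skipped
with a warning rather than aborting a run.

## Text analysis

The analysis chain is tokenize on non-letter/digit boundaries → case
fold → remove Norwegian stopwords (list versioned in
`data/stopwords_no.txt`) → stem. The stemmer implements the standard
three-step Norwegian snowball algorithm, applied repeatedly until a
fixed point: a single pass is not idempotent (pulsen → puls → pul),
and both the index and the query parser require the output to be a
true normal form. All golden test values were produced by this exact
chain and frozen.

Search semantics: boolean operators with adjacency binding as AND,
quoted phrases evaluated over post-stopword token positions, fuzzy
terms (`term~1`, `term~2`) expanded over the index vocabulary by
bounded Levenshtein distance, and metadata filters applied before
ranking. Relevance is BM25 (k1 = 1.2, b = 0.75, idf = ln(1 + (N − df +
0.5)/(df + 0.5))) summed over the non-negated query terms;
the final score multiplies relevance by a freshness factor
0.5^(age/half-life) with age measured against the newest document in
the index and a default half-life of 365 days. The combination rule
and the fuzzy parameters are this package's own choices — the
requirement was only that ranking reflect both relevance and
freshness; both are configuration-surfaced. Filter-only queries rank
purely by freshness.

## Extraction

Patterns live in YAML packs (`data/patterns_no.yaml` primary,
`data/patterns_en.yaml` for readability), not in code, because such
rules are always re-tuned per site. Each vital-sign spec carries an
ordered pattern list with a named value group, synonyms
(temperatur/temp/t; puls; BT/blodtrykk; vekt; høyde; BMI/KMI; ASA),
optional-colon/whitespace tolerance, decimal-comma normalization, and
an inclusive plausibility range: pulse 25–250 (two or three digits
required), temperature 30–45 °C, systolic 60–260 mmHg, diastolic
30–160 mmHg, weight 2–350 kg, height 40–230 cm, BMI 10–80, ASA 1–5.
Ranges are required by the method; the numbers are documented package
defaults. Out-of-range values are discarded and logged. The one-letter
synonym `t` only matches when followed by a value already in the
temperature range, to limit false positives. Blood pressure is
extracted as a pair from `NNN/NNN` forms; both components are
range-checked and a pair whose systolic does not exceed its diastolic
is discarded as implausible.

Status classification emits the key snippet (the first parenthesized
group of each pattern, by convention). Overlapping matches are
resolved by a documented precedence: question/recommendation forms
(uncertain) > negation (negative) > past-tense/quit forms (former) >
plain affirmation (positive); within equal priority the longer match
wins, then document order. Allergy statuses omit "former"; the
allergen substring is captured when adjacent to the trigger term.

## Synthetic substrate

The generator emulates the pilot's study conditions: 10 patients by
default, 1–6 encounters each (15 % left ongoing), 20–90 notes each
(so a default corpus has ~500 notes and some patients have many),
per-measure mention probabilities of 0.10–0.30 per note, smoking
statements in 35 % of notes (conditional status distribution
0.25/0.35/0.15/0.25 over positive/negative/former/uncertain), allergy
statements in 30 % (0.35/0.45/0.20), dates in 2013–2016, and a 0.4
probability of writing decimals with a comma. All randomness flows
through one PCG64 generator, so a seed reproduces byte-identical
outputs across platforms. Social security numbers have the right
11-digit shape but a checksum broken by construction.

Note text is assembled from sentence templates covering every synonym,
colon/no-colon and decimal-comma variant the extractor claims to
handle, plus filler sentences chosen to be inert under the pattern
packs; each planted item is recorded in a ground-truth table. With
noise 0 the shipped Norwegian pack recovers every planted item —
precision = recall = 1.0 per field — and this is asserted by the test
suite. The keyword-corpus and status-profile builders stage exact
scenario counts (36 matching "andre" documents; a 7/9/1
non-smoker/uncertain/ex-smoker profile) and verify the staging at
generation time.

What passing these tests shows: the pipeline is internally sound — the
patterns match exactly what the templates realize, the mappings
produce exactly the closed-form triple set, query answering equals
brute-force semantics. What it does not show: recall on real
Norwegian clinical prose, whose abbreviation habits, misspellings and
sentence structure are far more varied than any template library; the
noise knob (keyword typos) makes degradation measurable but is not a
model of real notes. The precision/recall table
(`evaluate_extraction`) exists precisely so a site can re-tune packs
against its own annotated sample.

## Record fusion

Measurement series merge all sources without deduplication — identical
(measure, value, timestamp) from two systems are both kept,
distinguishable by provenance, because suppressing one would silently
hide a corroborating source. Series are reverse chronological;
timestamp ties order document items before physician-order-entry
before EHR items, deterministically. A series summary reports latest
(maximum timestamp; ties resolve to the larger value, the conservative
choice for pre-operative screening), minimum and maximum, plus the
raw value sequence for sparkline rendering by a front end (rendering
itself is out of scope). Items with unparseable timestamps are
quarantined and counted, never dropped silently. Record assembly is
cached per patient, keyed on both backends' mutation counters, so
repeated access does not re-query and any backend change invalidates
exactly the affected cache entries.

## Numerical and degenerate-input conventions

* All result lists (query bindings, patient lists, predicate-object
  pairs) are sorted lexicographically; no contract depends on hash
  order.
* Empty inputs return empty structures, not errors: empty corpus,
  empty store, patient with no notes, empty measurement series
  (summary absent).
* Literal comparison in the store is exact on (lexical form,
  datatype); numeric literals are canonicalized at materialization
  time (`72.0` → `72`).
* Unknown individuals yield empty answers from the four query shapes;
  only record assembly for a patient absent from the graph is an
  error, because it signals a broken pipeline rather than an empty
  view.
* A query with an unbound predicate variable is rejected when
  inference is on: expanding an unknown property over the hierarchy
  closure has no well-defined finite answer set in this design.

## Problem sizes used by the automated checks

The test suite and the acceptance script size their simulations to
what the checks need: 100 random store/query instances (stores up to
~120 asserted triples) for graph-oracle agreement, 200 random
corpus/query cases for boolean-search agreement, a ~500-note noise-free
corpus for extraction recovery, and the 10-patient fixture for
materialization counts and record invariants. These mirror the pilot's
own scale (10 patients, hundreds of documents for some patients).

## Known limitations

* The local term roster and the relational schemas are plausible
  reconstructions; the original pilot's are not public.
* The R2RML subset has no join conditions; foreign-key templates must
  mint the referenced subject directly.
* Phrase queries ignore stopword positions (a phrase matches across an
  elided stopword).
* The extraction language packs cover the templated phenomena only;
  they are a starting point for site-specific tuning, not a clinical
  NLP system — by design the method is pattern-based, with no
  statistical models.
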