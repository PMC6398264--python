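"""Mine one clinical note for vitals, smoking and allergy status.

Runs the Norwegian pattern pack over a note and shows the paired
value/snippet fields the transformer populates, including negation
(non-smoker) and question-form (uncertain) handling.
"""

from carefuse.extraction import annotate_document, load_pattern_pack
from carefuse.text_index import DocumentRecord

pack = load_pattern_pack(language="no")
note = DocumentRecord(
    doc_id="demo-1", patient_id="1", doc_type="innkomstjournal",
    timestamp="2016-03-01T09:30:00",
    text=("Innkomst etter henvisning. Puls: 72. BT 130/85. Temp 37,8. "
          "Vekt 80 kg, høyde 180 cm. ASA 2. "
          "Røyker du? Ikke besvart. Ingen kjente allergier."))

annotated = annotate_document(note, pack)
for field in sorted(annotated.extracted):
    print(f"{field:28s} {annotated.extracted[field]}")
# Each *_value field holds extracted numbers/labels; the matching *_info
# field holds the verbatim source fragment, so every datum can be traced
# back into the note.  The smoking question classifies as "uncertain";
# the negated allergy statement as "negative".
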