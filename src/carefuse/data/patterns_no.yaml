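# Norwegian extraction pattern pack (primary).
#
# Vital-sign patterns carry a named (?P<value>...) group; key snippets of
# status patterns are the first parenthesized group.  All patterns are
# compiled case-insensitively.  Ranges are inclusive canonical-unit bounds;
# values outside are discarded and logged.  Decimal commas are accepted
# and normalized to decimal points.
language: "no"

vitals:
  - measure: pulse
    value_field: blood_pulse_value
    info_field: blood_pulse_info
    unit: bpm
    range: [25, 250]
    synonyms: [puls, pulsen]
    patterns:
      # pulse values require two or three digits
      - '\b(?:puls(?:en)?)\s*:?\s*(?P<value>\d{2,3})\b'

  - measure: temperature
    value_field: body_temperature_value
    info_field: body_temperature_info
    unit: C
    range: [30.0, 45.0]
    synonyms: [temperatur, temp, t]
    patterns:
      - '\b(?:temperatur(?:en)?|temp)\.?\s*:?\s*(?P<value>\d{2}(?:[.,]\d{1,2})?)\b'
      # the one-letter abbreviation "t" only with a plausible temperature value
      - '\bt\s*:?\s*(?P<value>(?:3\d|4[0-5])(?:[.,]\d{1,2})?)\b'

  - measure: weight
    value_field: body_weight_value
    info_field: body_weight_info
    unit: kg
    range: [2.0, 350.0]
    synonyms: [vekt, vekten]
    patterns:
      - '\b(?:vekt(?:en)?)\s*:?\s*(?P<value>\d{1,3}(?:[.,]\d{1,2})?)(?:\s*kg)?\b'

  - measure: height
    value_field: body_height_value
    info_field: body_height_info
    unit: cm
    range: [40.0, 230.0]
    synonyms: [høyde, hoyde, høgde]
    patterns:
      - '\b(?:h[øo]yde|høgde)\s*:?\s*(?P<value>\d{2,3})(?:\s*cm)?\b'

  - measure: bmi
    value_field: bmi_value
    info_field: bmi_info
    unit: kg/m2
    range: [10.0, 80.0]
    synonyms: [bmi, kmi, kroppsmasseindeks]
    patterns:
      - '\b(?:bmi|kmi|kroppsmasseindeks)\s*:?\s*(?P<value>\d{2}(?:[.,]\d{1,2})?)\b'

  - measure: asa
    value_field: asa_value
    info_field: asa_info
    unit: ASA
    range: [1, 5]
    synonyms: [asa, asa-klasse]
    patterns:
      - '\basa(?:[- ]?(?:klasse|gruppe))?\s*:?\s*(?P<value>[1-5])\b'

blood_pressure:
  systolic_field: systolic_bp_value
  systolic_info_field: systolic_bp_info
  diastolic_field: diastolic_bp_value
  diastolic_info_field: diastolic_bp_info
  unit: mmHg
  systolic_range: [60, 260]
  diastolic_range: [30, 160]
  synonyms: [bt, blodtrykk]
  patterns:
    - '\b(?:bt|blodtrykk(?:et)?)\s*:?\s*(?P<systolic>\d{2,3})\s*/\s*(?P<diastolic>\d{2,3})\b'

statuses:
  smoking:
    # precedence: question/recommendation (uncertain) > negation > former > plain positive
    - label: uncertain
      priority: 3
      patterns:
        - '(røyker du\s*\?)'
        - '(røykestatus\s*\?)'
        - '(røykevaner\s*\?)'
        - '(røykeslutt anbefales)'
        - '(anbefal\w* røykeslutt)'
        - '(røykfri før operasjon\w*)'
        - '(usikker\w* røykestatus)'
        - '(mulig røyker)'
    - label: negative
      priority: 2
      patterns:
        - '(røyker ikke)'
        - '(ikke-?røyker)'
        - '(aldri røykt)'
        - '(ingen røyking)'
        - '(benekter røyking)'
        - '(nekter for røyking)'
    - label: former
      priority: 1
      patterns:
        - '(tidligere røyker)'
        - '(eks-?røyker)'
        - '(sluttet å røyke)'
        - '(røykte tidligere)'
        - '(stumpet røyken)'
    - label: positive
      priority: 0
      patterns:
        - '(dagligrøyker)'
        - '(røyker daglig)'
        - '(røyker \d+ sigaretter)'
        - '\b(røyker)\b'

  allergy:
    - label: uncertain
      priority: 3
      patterns:
        - '(allergier\s*\?)'
        - '(allergi\s*\?)'
        - '(mulig allergi\w*)'
        - '(usikker\w* allergi\w*)'
        - '(kan ikke utelukke allergi\w*)'
    - label: negative
      priority: 2
      patterns:
        - '(ingen kjente allergier)'
        - '(ingen allergier)'
        - '(ingen allergi)'
        - '(ikke allergisk)'
        - '(benekter allergi\w*)'
    - label: positive
      priority: 0
      patterns:
        - '(allerg(?:i|isk) mot (?P<allergen>[\wæøåÆØÅ]+))'
        - '(kjent allergi:?\s*(?P<allergen>[\wæøåÆØÅ]+))'
        - '\b(allergisk reaksjon)\b'
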