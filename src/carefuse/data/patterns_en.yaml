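# English extraction pattern pack, shipped for testing and readability.
# Mirrors the structure of the Norwegian pack.
language: en

vitals:
  - measure: pulse
    value_field: blood_pulse_value
    info_field: blood_pulse_info
    unit: bpm
    range: [25, 250]
    synonyms: [pulse, heart rate, hr]
    patterns:
      - '\b(?:pulse|heart rate|hr)\s*:?\s*(?P<value>\d{2,3})\b'

  - measure: temperature
    value_field: body_temperature_value
    info_field: body_temperature_info
    unit: C
    range: [30.0, 45.0]
    synonyms: [temperature, temp, t]
    patterns:
      - '\b(?:temperature|temp)\.?\s*:?\s*(?P<value>\d{2}(?:[.,]\d{1,2})?)\b'
      - '\bt\s*:?\s*(?P<value>(?:3\d|4[0-5])(?:[.,]\d{1,2})?)\b'

  - measure: weight
    value_field: body_weight_value
    info_field: body_weight_info
    unit: kg
    range: [2.0, 350.0]
    synonyms: [weight]
    patterns:
      - '\bweight\s*:?\s*(?P<value>\d{1,3}(?:[.,]\d{1,2})?)(?:\s*kg)?\b'

  - measure: height
    value_field: body_height_value
    info_field: body_height_info
    unit: cm
    range: [40.0, 230.0]
    synonyms: [height]
    patterns:
      - '\bheight\s*:?\s*(?P<value>\d{2,3})(?:\s*cm)?\b'

  - measure: bmi
    value_field: bmi_value
    info_field: bmi_info
    unit: kg/m2
    range: [10.0, 80.0]
    synonyms: [bmi, body mass index]
    patterns:
      - '\b(?:bmi|body mass index)\s*:?\s*(?P<value>\d{2}(?:[.,]\d{1,2})?)\b'

  - measure: asa
    value_field: asa_value
    info_field: asa_info
    unit: ASA
    range: [1, 5]
    synonyms: [asa, asa class]
    patterns:
      - '\basa(?:[- ]?(?:class|grade))?\s*:?\s*(?P<value>[1-5])\b'

blood_pressure:
  systolic_field: systolic_bp_value
  systolic_info_field: systolic_bp_info
  diastolic_field: diastolic_bp_value
  diastolic_info_field: diastolic_bp_info
  unit: mmHg
  systolic_range: [60, 260]
  diastolic_range: [30, 160]
  synonyms: [bp, blood pressure]
  patterns:
    - '\b(?:bp|blood pressure)\s*:?\s*(?P<systolic>\d{2,3})\s*/\s*(?P<diastolic>\d{2,3})\b'

statuses:
  smoking:
    - label: uncertain
      priority: 3
      patterns:
        - '(do you smoke\s*\?)'
        - '(smoking status\s*\?)'
        - '(smoking cessation (?:is )?recommended)'
        - '(possible smoker)'
    - label: negative
      priority: 2
      patterns:
        - '(does not smoke)'
        - '(non-?smoker)'
        - '(never smoked)'
        - '(denies smoking)'
    - label: former
      priority: 1
      patterns:
        - '(former smoker)'
        - '(ex-?smoker)'
        - '(quit smoking)'
        - '(used to smoke)'
    - label: positive
      priority: 0
      patterns:
        - '(daily smoker)'
        - '(smokes \d+ cigarettes)'
        - '\b(smoker)\b'
        - '\b(smokes)\b'

  allergy:
    - label: uncertain
      priority: 3
      patterns:
        - '(allergies\s*\?)'
        - '(possible allerg\w+)'
        - '(uncertain allerg\w+)'
    - label: negative
      priority: 2
      patterns:
        - '(no known allergies)'
        - '(no allergies)'
        - '(not allergic)'
        - '(denies allerg\w+)'
    - label: positive
      priority: 0
      patterns:
        - '(allerg(?:y|ic) to (?P<allergen>\w+))'
        - '(known allergy:?\s*(?P<allergen>\w+))'
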