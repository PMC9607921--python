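# Entry archetype: treatment side effect reported by the patient in the app.
# Constraint model over the reference model; bindings name mapping-config
# sections whose SNOMED CT codes are admissible for the coded elements.
archetype_id: side_effect
concept: Secondary effect
constraints:
  - name: date
    value_kind: date
    required: true
  - name: finding
    value_kind: coded
    required: true
    binding: findings
  - name: value
    value_kind: text
    required: false
  - name: severity
    value_kind: coded
    required: true
    binding: severities
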