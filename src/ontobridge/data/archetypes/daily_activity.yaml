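# Entry archetype: daily physical activity tracked by the app.
archetype_id: daily_activity
concept: Daily activity
constraints:
  - name: date
    value_kind: date
    required: true
  - name: steps
    value_kind: quantity
    required: true
    unit: steps
  - name: calories
    value_kind: quantity
    required: true
    unit: kcal
  - name: duration
    value_kind: quantity
    required: true
    unit: min
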