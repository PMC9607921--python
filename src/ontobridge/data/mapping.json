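{
  "note": "Fixture mapping for the bundled pipeline. Only 'Wakefulness' -> 365930002 and the three severity codes are real SNOMED CT international-edition content; every other finding concept_id is a synthetic placeholder (99xxxxx range) standing in for an unpublished production value set.",
  "scheme_uri": "http://snomed.info/sct",
  "findings": {
    "Wakefulness": {"concept_id": "365930002", "display": "Wakefulness, function"},
    "náusea": {"concept_id": "9900001", "display": "Nausea (synthetic placeholder)"},
    "vómitos": {"concept_id": "9900002", "display": "Vomiting (synthetic placeholder)"},
    "fatiga": {"concept_id": "9900003", "display": "Fatigue (synthetic placeholder)"},
    "cefalea": {"concept_id": "9900004", "display": "Headache (synthetic placeholder)"},
    "mareo": {"concept_id": "9900005", "display": "Dizziness (synthetic placeholder)"},
    "dolor articular": {"concept_id": "9900006", "display": "Joint pain (synthetic placeholder)"},
    "fiebre": {"concept_id": "9900007", "display": "Fever (synthetic placeholder)"},
    "diarrea": {"concept_id": "9900008", "display": "Diarrhea (synthetic placeholder)"},
    "estreñimiento": {"concept_id": "9900009", "display": "Constipation (synthetic placeholder)"},
    "sofocos": {"concept_id": "9900010", "display": "Hot flush (synthetic placeholder)"},
    "pérdida de apetito": {"concept_id": "9900011", "display": "Loss of appetite (synthetic placeholder)"}
  },
  "severities": {
    "leve": {"concept_id": "255604002", "display": "Mild"},
    "moderada": {"concept_id": "6736007", "display": "Moderate"},
    "grave": {"concept_id": "24484000", "display": "Severe"}
  }
}
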