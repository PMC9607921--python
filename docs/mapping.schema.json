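{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://ontobridge.org/schemas/mapping.schema.json",
  "title": "Terminology mapping configuration",
  "description": "Binds local (Spanish) app literals to SNOMED CT concepts. Enforced at load time by the package's pydantic models; this document is the published description of the format.",
  "type": "object",
  "required": ["findings", "severities"],
  "properties": {
    "note": {"type": "string"},
    "scheme_uri": {
      "type": "string",
      "default": "http://snomed.info/sct",
      "description": "Coding-scheme base URI stamped on every coded value."
    },
    "findings": {"$ref": "#/$defs/section"},
    "severities": {"$ref": "#/$defs/section"}
  },
  "$defs": {
    "section": {
      "type": "object",
      "description": "Keys are local labels; duplicate labels after trim/casefold/accent-fold normalization are rejected.",
      "additionalProperties": {
        "type": "object",
        "required": ["concept_id"],
        "properties": {
          "concept_id": {"type": "string", "pattern": "^[0-9]+$"},
          "code_uri": {
            "type": "string",
            "description": "Defaults to http://snomed.info/id/<concept_id>; must end with the concept_id."
          },
          "display": {"type": "string", "description": "Preferred term; defaults to the local label."}
        },
        "additionalProperties": false
      }
    }
  }
}
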