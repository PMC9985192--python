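{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://example.org/phenocheck/check_report.schema.json",
  "title": "phenocheck check report",
  "type": "object",
  "required": ["overall", "results"],
  "properties": {
    "overall": {"type": "string", "enum": ["pass", "fail"]},
    "generated": {"type": "string"},
    "inputs": {"type": "array", "items": {"type": "string"}},
    "config": {"type": "object"},
    "results": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["check", "status", "message", "details", "info"],
        "properties": {
          "check": {"type": "string"},
          "status": {"type": "string", "enum": ["pass", "fail", "not_run"]},
          "message": {"type": "string"},
          "details": {"$ref": "#/$defs/findings"},
          "info": {"$ref": "#/$defs/findings"}
        }
      }
    }
  },
  "$defs": {
    "findings": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["variable", "row", "value", "note"],
        "properties": {
          "variable": {"type": ["string", "null"]},
          "row": {"type": ["integer", "null"]},
          "value": {"type": ["string", "null"]},
          "note": {"type": "string"}
        }
      }
    }
  }
}
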