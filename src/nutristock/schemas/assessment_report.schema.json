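{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://example.invalid/nutristock/assessment_report.schema.json",
  "title": "Stockpile nutritional assessment report",
  "type": "object",
  "required": ["municipality", "victims", "scenario", "rows"],
  "properties": {
    "municipality": {"type": "string"},
    "victims": {"type": "integer", "minimum": 0},
    "scenario": {
      "type": "object",
      "required": ["affected_fraction", "days", "profile", "victim_rounding", "mark_boundary"],
      "properties": {
        "affected_fraction": {"type": "number", "minimum": 0, "maximum": 1},
        "days": {"type": "integer", "minimum": 1},
        "profile": {"enum": ["full", "shelter5"]},
        "victim_rounding": {"enum": ["ceil", "round", "floor"]},
        "mark_boundary": {"enum": ["inclusive", "exclusive"]}
      }
    },
    "rows": {
      "type": "array",
      "items": {
        "type": "object",
        "required": [
          "nutrient", "name", "unit", "required", "supplied",
          "ratio_pct", "ratio_pct_display", "mark", "mark_display", "people_covered"
        ],
        "properties": {
          "nutrient": {"type": "string"},
          "name": {"type": "string"},
          "unit": {"type": "string"},
          "required": {"type": "number", "minimum": 0},
          "supplied": {"type": "number", "minimum": 0},
          "ratio_pct": {
            "oneOf": [{"type": "number", "minimum": 0}, {"const": "inf"}]
          },
          "ratio_pct_display": {"type": "string"},
          "mark": {"enum": ["O", "x"]},
          "mark_display": {"enum": ["Ο", "×"]},
          "people_covered": {"type": "integer", "minimum": 0}
        }
      }
    }
  }
}
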