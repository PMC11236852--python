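{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Scorecard configuration document",
  "type": "object",
  "required": ["id", "name", "nominal_max", "indicators"],
  "properties": {
    "id": {"type": "string"},
    "name": {"type": "string"},
    "nominal_max": {"type": "number", "exclusiveMinimum": 0},
    "declared_point_loss": {"type": "number", "minimum": 0},
    "indicators": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["id", "group", "categories"],
        "properties": {
          "id": {"type": "string"},
          "name": {"type": "string"},
          "group": {"enum": ["vegetation", "hydrology", "site_management"]},
          "method": {"type": "string"},
          "provenance": {"enum": ["printed", "supplementary", "reconstructed"]},
          "categories": {
            "type": "array",
            "minItems": 2,
            "items": {
              "type": "object",
              "required": ["label", "points"],
              "properties": {
                "label": {"type": "string"},
                "description": {"type": "string"},
                "points": {"type": "number"},
                "provenance": {"enum": ["printed", "supplementary", "reconstructed"]}
              }
            }
          }
        }
      }
    },
    "aliases": {
      "type": "object",
      "additionalProperties": {"type": "string"}
    }
  }
}
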