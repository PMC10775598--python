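{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "artdose statistics report",
  "type": "object",
  "required": ["fig1a", "fig1c", "fig2", "fig3", "fig4a", "fig4b", "table2"],
  "properties": {
    "fig1a": {
      "type": "object",
      "required": ["ecdf_scheduled", "ecdf_adaptive", "median_eud_scheduled",
                   "median_eud_adaptive", "scale_test", "location_test"],
      "properties": {
        "ecdf_scheduled": {"$ref": "#/$defs/ecdf"},
        "ecdf_adaptive": {"$ref": "#/$defs/ecdf"},
        "median_eud_scheduled": {"type": "number"},
        "median_eud_adaptive": {"type": "number"},
        "scale_test": {"$ref": "#/$defs/test_result"},
        "location_test": {"$ref": "#/$defs/test_result"}
      }
    },
    "fig1c": {
      "type": "object",
      "required": ["ecdf_scheduled", "ecdf_adaptive", "signed_rank"],
      "properties": {
        "ecdf_scheduled": {"$ref": "#/$defs/ecdf"},
        "ecdf_adaptive": {"$ref": "#/$defs/ecdf"},
        "signed_rank": {"$ref": "#/$defs/test_result"}
      }
    },
    "fig2": {"type": "object"},
    "fig3": {"type": "object"},
    "fig4a": {
      "type": "object",
      "required": ["per_parameter", "median_inter_p95", "median_intra_p95"],
      "properties": {
        "per_parameter": {"type": "array"},
        "median_inter_p95": {"type": "number"},
        "median_intra_p95": {"type": "number"}
      }
    },
    "fig4b": {"type": "object"},
    "table2": {"type": "array"}
  },
  "$defs": {
    "ecdf": {
      "type": "object",
      "required": ["x", "F"],
      "properties": {
        "x": {"type": "array", "items": {"type": "number"}},
        "F": {"type": "array", "items": {"type": "number"}}
      }
    },
    "test_result": {
      "type": "object",
      "required": ["method", "statistic", "p_value", "n"],
      "properties": {
        "method": {"type": "string"},
        "statistic": {"type": "number"},
        "p_value": {"type": "number"},
        "n": {"type": "number"}
      }
    }
  }
}
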