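{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "azadem run-all combined summary",
  "type": "object",
  "required": [
    "seed",
    "global_methylation",
    "compartments",
    "promoters",
    "response_clusters",
    "induced_fraction_pct",
    "peaks",
    "intron_retention"
  ],
  "properties": {
    "seed": {"type": "integer"},
    "config_hash": {"type": "string"},
    "global_methylation": {
      "type": "object",
      "required": ["luma_percent_by_condition", "acute_dose_response"],
      "properties": {
        "luma_percent_by_condition": {
          "type": "object",
          "additionalProperties": {"type": "number", "minimum": 0, "maximum": 100}
        },
        "acute_dose_response": {"type": "object"}
      }
    },
    "compartments": {
      "type": "object",
      "required": [
        "enrichment_response_x_expression",
        "enrichment_response_x_methylation",
        "n_windows"
      ],
      "properties": {
        "n_windows": {"type": "integer", "minimum": 0},
        "enrichment_response_x_expression": {"$ref": "#/$defs/enrichment"},
        "enrichment_response_x_methylation": {"$ref": "#/$defs/enrichment"}
      }
    },
    "promoters": {
      "type": "object",
      "required": ["cg_cutoff", "class_counts", "lcg_fraction", "n_methylated_lcg"],
      "properties": {
        "cg_cutoff": {"type": "number", "minimum": 0},
        "class_counts": {
          "type": "object",
          "required": ["HCG", "LCG"],
          "properties": {
            "HCG": {"type": "integer", "minimum": 0},
            "LCG": {"type": "integer", "minimum": 0}
          }
        },
        "lcg_fraction": {"type": "number", "minimum": 0, "maximum": 1},
        "n_methylated_lcg": {"type": "integer", "minimum": 0}
      }
    },
    "response_clusters": {
      "type": "object",
      "required": ["k", "n_units", "proportions_pct", "loss_total_pct", "gain_total_pct"],
      "properties": {
        "k": {"type": "integer", "minimum": 1},
        "n_units": {"type": "integer", "minimum": 0},
        "counts": {"type": "object", "additionalProperties": {"type": "integer"}},
        "proportions_pct": {"type": "object", "additionalProperties": {"type": "number"}},
        "loss_total_pct": {"type": "number", "minimum": 0, "maximum": 100},
        "gain_total_pct": {"type": "number", "minimum": 0, "maximum": 100}
      }
    },
    "induced_fraction_pct": {"type": "number", "minimum": 0, "maximum": 100},
    "peaks": {
      "type": "object",
      "required": ["counts", "new_peak_context_counts", "silent_activation"],
      "properties": {
        "counts": {"type": "object", "additionalProperties": {"type": "integer"}},
        "new_peak_context_counts": {
          "type": "object",
          "additionalProperties": {"type": "integer"}
        },
        "new_intragenic_meth_shift": {"type": "object"},
        "silent_activation": {
          "type": "object",
          "required": [
            "fraction_silent_before",
            "fraction_silent_after",
            "n_activated",
            "n_genes"
          ]
        },
        "intragenic_enrichment": {"type": "object"}
      }
    },
    "intron_retention": {
      "type": "object",
      "required": ["shift_report", "n_genes"],
      "properties": {
        "n_genes": {"type": "integer", "minimum": 0},
        "shift_report": {
          "type": "object",
          "required": ["n_increased", "n_decreased", "systematic_shift", "verdict"]
        },
        "planted_recovery": {"type": ["number", "null"]}
      }
    }
  },
  "$defs": {
    "enrichment": {
      "type": "object",
      "required": ["table", "odds_ratio", "p_value"],
      "properties": {
        "table": {
          "type": "array",
          "items": {"type": "array", "items": {"type": "integer"}}
        },
        "odds_ratio": {"type": ["number", "null"]},
        "p_value": {"type": "number", "minimum": 0, "maximum": 1}
      }
    }
  }
}
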