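{
  "type": "object",
  "required": ["meta", "effects", "pcurve", "pcurve_error", "provenance"],
  "properties": {
    "meta": {
      "type": "object",
      "required": ["k", "pooled_d", "pooled_se", "ci_low", "ci_high", "tau2", "Q", "q_df", "q_p", "i2", "i2_low", "i2_high"],
      "properties": {
        "k": {"type": "integer"},
        "pooled_d": {"type": "number"},
        "pooled_se": {"type": "number"},
        "ci_low": {"type": "number"},
        "ci_high": {"type": "number"},
        "tau2": {"type": "number"},
        "Q": {"type": "number"},
        "q_df": {"type": "integer"},
        "q_p": {"type": "number"},
        "i2": {"type": "number"},
        "i2_low": {"type": "number"},
        "i2_high": {"type": "number"}
      }
    },
    "effects": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["study_id", "d", "v", "se", "z", "p"],
        "properties": {
          "study_id": {"type": "string"},
          "d": {"type": "number"},
          "v": {"type": "number"},
          "se": {"type": "number"},
          "z": {"type": "number"},
          "p": {"type": "number"}
        }
      }
    },
    "pcurve": {
      "type": ["object", "null"],
      "required": ["tests", "n_significant", "n_excluded", "inference", "pp_values"],
      "properties": {
        "tests": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["chi2", "df", "p", "label"],
            "properties": {
              "chi2": {"type": "number"},
              "df": {"type": "integer"},
              "p": {"type": "number"},
              "label": {"enum": ["right_skew", "flatter_than_33", "left_skew"]}
            }
          }
        },
        "n_significant": {"type": "integer"},
        "n_excluded": {"type": "integer"},
        "inference": {"type": "string"},
        "pp_values": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["study_id", "p_obs", "pp_right", "pp_33", "pp_left", "winsorized"],
            "properties": {
              "study_id": {"type": "string"},
              "p_obs": {"type": "number"},
              "pp_right": {"type": "number"},
              "pp_33": {"type": "number"},
              "pp_left": {"type": "number"},
              "winsorized": {"type": "object"}
            }
          }
        }
      }
    },
    "pcurve_error": {"type": ["string", "null"]},
    "provenance": {
      "type": "object",
      "required": ["package_version", "config", "input_digest", "n_studies_input"],
      "properties": {
        "package_version": {"type": "string"},
        "config": {"type": "object"},
        "input_digest": {"type": "string"},
        "n_studies_input": {"type": "integer"}
      }
    }
  }
}
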