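{
  "type": "object",
  "required": ["schema_version", "config", "patients", "cohort"],
  "properties": {
    "schema_version": {"type": "string"},
    "config": {
      "type": "object",
      "required": ["fit_policy", "rmblr", "tumors_in_bone", "dose_limits_Gy"],
      "properties": {
        "fit_policy": {"type": "string"},
        "rmblr": {"type": "number"},
        "tumors_in_bone": {"type": "boolean"},
        "dose_limits_Gy": {
          "type": "object",
          "additionalProperties": {"type": "number"}
        },
        "input_hashes": {
          "type": "object",
          "additionalProperties": {"type": "string"}
        }
      }
    },
    "patients": {
      "type": "array",
      "items": {
        "type": "object",
        "required": [
          "patient_id",
          "injected_activity_MBq",
          "residence_times_h",
          "organ_doses_Gy_per_GBq",
          "tumor_doses_Gy_per_GBq",
          "mta_GBq",
          "limiting_organ",
          "per_organ_mta_GBq",
          "therapeutic_indices"
        ],
        "properties": {
          "patient_id": {"type": "string"},
          "injected_activity_MBq": {"type": "number"},
          "residence_times_h": {
            "type": "object",
            "additionalProperties": {"type": "number"}
          },
          "organ_doses_Gy_per_GBq": {
            "type": "object",
            "additionalProperties": {"type": "number"}
          },
          "tumor_doses_Gy_per_GBq": {
            "type": "array",
            "items": {"type": "number"}
          },
          "mta_GBq": {"type": "number"},
          "limiting_organ": {"type": "string"},
          "per_organ_mta_GBq": {
            "type": "object",
            "additionalProperties": {"type": "number"}
          },
          "therapeutic_indices": {
            "type": "object",
            "additionalProperties": {"type": "number"}
          },
          "flags": {"type": "array", "items": {"type": "string"}}
        }
      }
    },
    "cohort": {
      "type": "object",
      "required": ["organ_stats", "mta_stats_GBq", "excluded_patients"],
      "properties": {
        "organ_stats": {
          "type": "object",
          "additionalProperties": {
            "type": "object",
            "required": ["median", "mean", "sd"],
            "properties": {
              "median": {"type": "number"},
              "mean": {"type": "number"},
              "sd": {"type": "number"}
            }
          }
        },
        "mta_stats_GBq": {
          "type": "object",
          "required": ["median", "mean", "sd"],
          "properties": {
            "median": {"type": "number"},
            "mean": {"type": "number"},
            "sd": {"type": "number"}
          }
        },
        "excluded_patients": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["patient_id", "reason"],
            "properties": {
              "patient_id": {"type": "string"},
              "reason": {"type": "string"}
            }
          }
        }
      }
    }
  }
}
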