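{
  "$defs": {
    "AuditSection": {
      "description": "Audit results; optional blocks absent when a stage was not run.",
      "properties": {
        "counterfactual": {
          "additionalProperties": {
            "additionalProperties": true,
            "type": "object"
          },
          "title": "Counterfactual",
          "type": "object"
        },
        "cv": {
          "additionalProperties": {
            "additionalProperties": true,
            "type": "object"
          },
          "title": "Cv",
          "type": "object"
        },
        "fairness": {
          "additionalProperties": {
            "additionalProperties": true,
            "type": "object"
          },
          "title": "Fairness",
          "type": "object"
        },
        "permutation": {
          "additionalProperties": {
            "additionalProperties": true,
            "type": "object"
          },
          "title": "Permutation",
          "type": "object"
        },
        "sensitivity": {
          "anyOf": [
            {
              "items": {
                "additionalProperties": true,
                "type": "object"
              },
              "type": "array"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Sensitivity"
        }
      },
      "title": "AuditSection",
      "type": "object"
    },
    "DataProvenance": {
      "properties": {
        "cohort_spec": {
          "additionalProperties": true,
          "title": "Cohort Spec",
          "type": "object"
        },
        "demographic_composition": {
          "additionalProperties": true,
          "title": "Demographic Composition",
          "type": "object"
        },
        "feature_descriptions": {
          "additionalProperties": {
            "type": "string"
          },
          "title": "Feature Descriptions",
          "type": "object"
        },
        "known_limitations": {
          "items": {
            "type": "string"
          },
          "title": "Known Limitations",
          "type": "array"
        },
        "seed": {
          "title": "Seed",
          "type": "integer"
        }
      },
      "required": [
        "cohort_spec",
        "seed",
        "feature_descriptions",
        "demographic_composition"
      ],
      "title": "DataProvenance",
      "type": "object"
    },
    "DevelopmentLogEntry": {
      "properties": {
        "config": {
          "additionalProperties": true,
          "title": "Config",
          "type": "object"
        },
        "metrics": {
          "additionalProperties": true,
          "title": "Metrics",
          "type": "object"
        },
        "rationale": {
          "default": "",
          "title": "Rationale",
          "type": "string"
        },
        "step": {
          "title": "Step",
          "type": "string"
        },
        "timestamp": {
          "title": "Timestamp",
          "type": "string"
        }
      },
      "required": [
        "step",
        "timestamp",
        "config"
      ],
      "title": "DevelopmentLogEntry",
      "type": "object"
    },
    "InferenceLogEntry": {
      "description": "One hash-chained per-prediction record.",
      "properties": {
        "entry_hash": {
          "pattern": "^[0-9a-f]{64}$",
          "title": "Entry Hash",
          "type": "string"
        },
        "entry_id": {
          "title": "Entry Id",
          "type": "string"
        },
        "model_version": {
          "title": "Model Version",
          "type": "string"
        },
        "patient_ref": {
          "title": "Patient Ref",
          "type": "string"
        },
        "payload": {
          "additionalProperties": true,
          "title": "Payload",
          "type": "object"
        },
        "prev_hash": {
          "pattern": "^[0-9a-f]{64}$",
          "title": "Prev Hash",
          "type": "string"
        },
        "sequence": {
          "minimum": 1,
          "title": "Sequence",
          "type": "integer"
        },
        "timestamp": {
          "title": "Timestamp",
          "type": "string"
        }
      },
      "required": [
        "sequence",
        "entry_id",
        "timestamp",
        "model_version",
        "patient_ref",
        "payload",
        "prev_hash",
        "entry_hash"
      ],
      "title": "InferenceLogEntry",
      "type": "object"
    }
  },
  "properties": {
    "audit": {
      "$ref": "#/$defs/AuditSection"
    },
    "chain_head": {
      "default": "0000000000000000000000000000000000000000000000000000000000000000",
      "title": "Chain Head",
      "type": "string"
    },
    "complete": {
      "default": true,
      "title": "Complete",
      "type": "boolean"
    },
    "data_provenance": {
      "$ref": "#/$defs/DataProvenance"
    },
    "inference_log": {
      "items": {
        "$ref": "#/$defs/InferenceLogEntry"
      },
      "title": "Inference Log",
      "type": "array"
    },
    "model_development": {
      "items": {
        "$ref": "#/$defs/DevelopmentLogEntry"
      },
      "title": "Model Development",
      "type": "array"
    },
    "schema_version": {
      "default": "1.0",
      "title": "Schema Version",
      "type": "string"
    }
  },
  "required": [
    "data_provenance",
    "audit"
  ],
  "title": "AFPRDocument",
  "type": "object"
}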