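{
  "description": "Schema of the run-all report (published as report_schema.json).",
  "properties": {
    "config": {
      "additionalProperties": true,
      "title": "Config",
      "type": "object"
    },
    "thresholds_applied": {
      "additionalProperties": {
        "type": "number"
      },
      "title": "Thresholds Applied",
      "type": "object"
    },
    "n_subjects": {
      "title": "N Subjects",
      "type": "integer"
    },
    "stable_features": {
      "items": {
        "type": "string"
      },
      "title": "Stable Features",
      "type": "array"
    },
    "selected_fb": {
      "items": {
        "type": "string"
      },
      "title": "Selected Fb",
      "type": "array"
    },
    "selected_aip": {
      "items": {
        "type": "string"
      },
      "title": "Selected Aip",
      "type": "array"
    },
    "univariate_summary": {
      "additionalProperties": {
        "additionalProperties": {
          "type": "number"
        },
        "type": "object"
      },
      "title": "Univariate Summary",
      "type": "object"
    },
    "model_median_ci": {
      "additionalProperties": {
        "type": "number"
      },
      "title": "Model Median Ci",
      "type": "object"
    },
    "pairwise_p": {
      "additionalProperties": {
        "additionalProperties": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ]
        },
        "type": "object"
      },
      "title": "Pairwise P",
      "type": "object"
    },
    "n_failed_splits": {
      "additionalProperties": {
        "type": "integer"
      },
      "title": "N Failed Splits",
      "type": "object"
    },
    "checksums": {
      "additionalProperties": {
        "type": "string"
      },
      "title": "Checksums",
      "type": "object"
    }
  },
  "required": [
    "config",
    "thresholds_applied",
    "n_subjects",
    "stable_features",
    "selected_fb",
    "selected_aip",
    "univariate_summary",
    "model_median_ci",
    "pairwise_p",
    "n_failed_splits",
    "checksums"
  ],
  "title": "ReportModel",
  "type": "object"
}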