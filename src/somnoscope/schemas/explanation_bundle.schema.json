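{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "additionalProperties": false,
  "properties": {
    "alpha": {
      "additionalProperties": false,
      "properties": {
        "values": {
          "items": {
            "type": "number"
          },
          "type": "array"
        }
      },
      "required": [
        "values"
      ],
      "type": "object"
    },
    "boxes": {
      "items": {
        "additionalProperties": false,
        "properties": {
          "end": {
            "minimum": 1,
            "type": "integer"
          },
          "pattern": {
            "enum": [
              "alpha",
              "theta",
              "delta",
              "sawtooth",
              "vertex_sharp",
              "spindle",
              "kcomplex"
            ]
          },
          "score": {
            "type": "number"
          },
          "start": {
            "minimum": 0,
            "type": "integer"
          }
        },
        "required": [
          "start",
          "end",
          "pattern",
          "score"
        ],
        "type": "object"
      },
      "type": "array"
    },
    "delta": {
      "additionalProperties": false,
      "properties": {
        "blocks": {
          "items": {
            "items": {
              "type": "integer"
            },
            "maxItems": 2,
            "minItems": 2,
            "type": "array"
          },
          "type": "array"
        },
        "count": {
          "minimum": 0,
          "type": "integer"
        },
        "coverage": {
          "maximum": 1,
          "minimum": 0,
          "type": "number"
        },
        "meets_n3_rule": {
          "type": "boolean"
        }
      },
      "required": [
        "blocks",
        "count",
        "coverage",
        "meets_n3_rule"
      ],
      "type": "object"
    },
    "epoch_index": {
      "minimum": 0,
      "type": "integer"
    },
    "highlights": {
      "additionalProperties": false,
      "properties": {
        "regions": {
          "items": {
            "items": {
              "type": "integer"
            },
            "maxItems": 2,
            "minItems": 2,
            "type": "array"
          },
          "type": "array"
        }
      },
      "required": [
        "regions"
      ],
      "type": "object"
    },
    "predicted_stage": {
      "enum": [
        "W",
        "N1",
        "N2",
        "N3",
        "REM"
      ]
    },
    "probabilities": {
      "additionalProperties": false,
      "properties": {
        "N1": {
          "maximum": 1,
          "minimum": 0,
          "type": "number"
        },
        "N2": {
          "maximum": 1,
          "minimum": 0,
          "type": "number"
        },
        "N3": {
          "maximum": 1,
          "minimum": 0,
          "type": "number"
        },
        "REM": {
          "maximum": 1,
          "minimum": 0,
          "type": "number"
        },
        "W": {
          "maximum": 1,
          "minimum": 0,
          "type": "number"
        }
      },
      "required": [
        "W",
        "N1",
        "N2",
        "N3",
        "REM"
      ],
      "type": "object"
    }
  },
  "required": [
    "epoch_index",
    "predicted_stage",
    "probabilities"
  ],
  "title": "ExplanationBundle",
  "type": "object"
}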