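{
  "$defs": {
    "EvalSection": {
      "additionalProperties": false,
      "properties": {
        "n_segments": {
          "default": 4,
          "title": "N Segments",
          "type": "integer"
        },
        "n_single_epochs": {
          "default": 30,
          "title": "N Single Epochs",
          "type": "integer"
        },
        "segment_minutes": {
          "default": 15.0,
          "title": "Segment Minutes",
          "type": "number"
        }
      },
      "title": "EvalSection",
      "type": "object"
    },
    "ExplainerSection": {
      "additionalProperties": false,
      "properties": {
        "calibration_epochs": {
          "default": 100,
          "title": "Calibration Epochs",
          "type": "integer"
        },
        "saliency_percentile": {
          "default": 90.0,
          "title": "Saliency Percentile",
          "type": "number"
        }
      },
      "title": "ExplainerSection",
      "type": "object"
    },
    "RefinementSection": {
      "additionalProperties": false,
      "properties": {
        "delta_cutoff_hz": {
          "default": 4.0,
          "title": "Delta Cutoff Hz",
          "type": "number"
        },
        "kcomplex_cutoff_hz": {
          "default": 4.0,
          "title": "Kcomplex Cutoff Hz",
          "type": "number"
        }
      },
      "title": "RefinementSection",
      "type": "object"
    },
    "SimulateSection": {
      "additionalProperties": false,
      "properties": {
        "delta_coverage": {
          "default": 0.35,
          "title": "Delta Coverage",
          "type": "number"
        },
        "n_epochs": {
          "default": 60,
          "title": "N Epochs",
          "type": "integer"
        },
        "n_recordings": {
          "default": 20,
          "title": "N Recordings",
          "type": "integer"
        },
        "noise_sd": {
          "default": 5.0,
          "title": "Noise Sd",
          "type": "number"
        },
        "sweat": {
          "default": false,
          "title": "Sweat",
          "type": "boolean"
        }
      },
      "title": "SimulateSection",
      "type": "object"
    },
    "StagerSection": {
      "additionalProperties": false,
      "properties": {
        "batch_size": {
          "default": 64,
          "title": "Batch Size",
          "type": "integer"
        },
        "freeze_templates": {
          "default": true,
          "title": "Freeze Templates",
          "type": "boolean"
        },
        "hidden": {
          "default": 32,
          "title": "Hidden",
          "type": "integer"
        },
        "kernel_len": {
          "default": 100,
          "title": "Kernel Len",
          "type": "integer"
        },
        "learning_rate": {
          "default": 0.001,
          "title": "Learning Rate",
          "type": "number"
        },
        "n_free_filters": {
          "default": 8,
          "title": "N Free Filters",
          "type": "integer"
        },
        "pool_len": {
          "default": 100,
          "title": "Pool Len",
          "type": "integer"
        },
        "train_epochs": {
          "default": 30,
          "title": "Train Epochs",
          "type": "integer"
        }
      },
      "title": "StagerSection",
      "type": "object"
    }
  },
  "additionalProperties": false,
  "properties": {
    "epoch_duration": {
      "default": 30.0,
      "title": "Epoch Duration",
      "type": "number"
    },
    "eval": {
      "$ref": "#/$defs/EvalSection"
    },
    "explainer": {
      "$ref": "#/$defs/ExplainerSection"
    },
    "fs": {
      "default": 100.0,
      "title": "Fs",
      "type": "number"
    },
    "refinement": {
      "$ref": "#/$defs/RefinementSection"
    },
    "seed": {
      "default": 0,
      "title": "Seed",
      "type": "integer"
    },
    "simulate": {
      "$ref": "#/$defs/SimulateSection"
    },
    "stager": {
      "$ref": "#/$defs/StagerSection"
    }
  },
  "title": "RunConfig",
  "type": "object"
}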