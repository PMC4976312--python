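{
  "$defs": {
    "PipelineConfig": {
      "description": "Run settings; file paths may point at externally produced tables.",
      "properties": {
        "seed": {
          "default": 0,
          "title": "Seed",
          "type": "integer"
        },
        "n_individuals": {
          "default": 1792,
          "title": "N Individuals",
          "type": "integer"
        },
        "low_set": {
          "default": [
            2,
            3
          ],
          "items": {
            "type": "integer"
          },
          "title": "Low Set",
          "type": "array"
        },
        "ambiguity_tolerance": {
          "default": 0.3,
          "title": "Ambiguity Tolerance",
          "type": "number"
        },
        "efficiency": {
          "default": 1.94,
          "title": "Efficiency",
          "type": "number"
        },
        "em_tolerance": {
          "default": 1e-05,
          "title": "Em Tolerance",
          "type": "number"
        },
        "em_max_iterations": {
          "default": 200,
          "title": "Em Max Iterations",
          "type": "integer"
        },
        "stages": {
          "default": [
            "simulate",
            "callcn",
            "assoc",
            "emld",
            "expr"
          ],
          "items": {
            "type": "string"
          },
          "title": "Stages",
          "type": "array"
        },
        "genotype_tsv": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Genotype Tsv"
        },
        "ct_tsv": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Ct Tsv"
        },
        "calibrator_tsv": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Calibrator Tsv"
        },
        "expression_tsv": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Expression Tsv"
        }
      },
      "title": "PipelineConfig",
      "type": "object"
    }
  },
  "properties": {
    "version": {
      "title": "Version",
      "type": "string"
    },
    "config": {
      "$ref": "#/$defs/PipelineConfig"
    },
    "generated_at": {
      "anyOf": [
        {
          "type": "string"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Generated At"
    },
    "warnings": {
      "items": {
        "type": "string"
      },
      "title": "Warnings",
      "type": "array"
    },
    "stages": {
      "additionalProperties": {
        "additionalProperties": true,
        "type": "object"
      },
      "title": "Stages",
      "type": "object"
    }
  },
  "required": [
    "version",
    "config"
  ],
  "title": "RunReport",
  "type": "object"
}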