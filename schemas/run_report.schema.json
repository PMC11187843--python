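{
  "$defs": {
    "StageRecord": {
      "properties": {
        "metrics": {
          "additionalProperties": true,
          "title": "Metrics",
          "type": "object"
        },
        "reason": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Reason"
        },
        "stage": {
          "title": "Stage",
          "type": "string"
        },
        "status": {
          "title": "Status",
          "type": "string"
        },
        "tables": {
          "items": {
            "type": "string"
          },
          "title": "Tables",
          "type": "array"
        }
      },
      "required": [
        "stage",
        "status"
      ],
      "title": "StageRecord",
      "type": "object"
    }
  },
  "description": "Machine-readable pipeline report: one record per stage + provenance.",
  "properties": {
    "config_hash": {
      "title": "Config Hash",
      "type": "string"
    },
    "seed": {
      "title": "Seed",
      "type": "integer"
    },
    "stages": {
      "items": {
        "$ref": "#/$defs/StageRecord"
      },
      "title": "Stages",
      "type": "array"
    },
    "version": {
      "title": "Version",
      "type": "string"
    },
    "warnings": {
      "items": {
        "type": "string"
      },
      "title": "Warnings",
      "type": "array"
    }
  },
  "required": [
    "version",
    "config_hash",
    "seed",
    "stages"
  ],
  "title": "RunReport",
  "type": "object"
}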