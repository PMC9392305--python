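{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "bedflex pathway configuration",
  "description": "Declarative model of a multi-unit bed pathway with two-tier (allocated + flex) capacity. Time unit: days. Loaded from YAML or JSON.",
  "type": "object",
  "required": ["arrivals", "units"],
  "properties": {
    "name": {"type": "string"},
    "arrivals": {
      "type": "object",
      "required": ["base_rate", "entry_unit"],
      "properties": {
        "base_rate": {"type": "number", "exclusiveMinimum": 0, "description": "arrivals/day before growth"},
        "growth_factor": {"type": "number", "minimum": 0, "default": 1.0},
        "mimic_fraction": {"type": "number", "minimum": 0, "maximum": 1, "default": 0.0},
        "entry_unit": {"type": "string"},
        "entry_policy": {"enum": ["wait", "loss"], "default": "wait"}
      }
    },
    "sinks": {
      "type": "array",
      "items": {"type": "string"},
      "description": "community destinations with unbounded capacity (e.g. P0, P1, P1plus, P3, home)"
    },
    "units": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["name", "allocated_beds", "los", "routes"],
        "properties": {
          "name": {"type": "string"},
          "allocated_beds": {"type": "integer", "minimum": 0},
          "flex_beds": {"type": "integer", "minimum": 0, "default": 0},
          "los": {
            "description": "either a LOS spec (applied to strokes) or a {stroke, mimic} map of LOS specs",
            "oneOf": [
              {"$ref": "#/$defs/los"},
              {
                "type": "object",
                "required": ["stroke"],
                "properties": {
                  "stroke": {"$ref": "#/$defs/los"},
                  "mimic": {"$ref": "#/$defs/los"}
                },
                "additionalProperties": false
              }
            ]
          },
          "routes": {
            "description": "either a route list (applied to strokes) or a {stroke, mimic} map of route lists; probabilities per class must sum to 1",
            "oneOf": [
              {"$ref": "#/$defs/routes"},
              {
                "type": "object",
                "required": ["stroke"],
                "properties": {
                  "stroke": {"$ref": "#/$defs/routes"},
                  "mimic": {"$ref": "#/$defs/routes"}
                },
                "additionalProperties": false
              }
            ]
          }
        }
      }
    },
    "settings": {
      "type": "object",
      "properties": {
        "replications": {"type": "integer", "minimum": 1, "default": 1500},
        "horizon": {"type": "number", "exclusiveMinimum": 0, "default": 365},
        "warmup": {"type": "number", "minimum": 0, "default": 100},
        "base_seed": {"type": "integer", "default": 0}
      }
    }
  },
  "$defs": {
    "los": {
      "type": "object",
      "required": ["family", "mean"],
      "properties": {
        "family": {"enum": ["exponential", "lognormal", "gamma", "fixed"]},
        "mean": {"type": "number", "exclusiveMinimum": 0, "description": "days"},
        "cv": {"type": "number", "minimum": 0, "description": "coefficient of variation; forced to 1 for exponential and 0 for fixed"}
      }
    },
    "routes": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["destination", "probability"],
        "properties": {
          "destination": {"type": "string", "description": "unit name or sink name"},
          "probability": {"type": "number", "minimum": 0, "maximum": 1},
          "fixed_delay": {"type": "number", "minimum": 0, "default": 0, "description": "days held in the source bed after readiness"}
        }
      }
    }
  }
}
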