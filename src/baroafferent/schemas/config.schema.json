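{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "baroafferent configuration blocks",
  "description": "Shapes of the JSON configuration blocks accepted by the CLI and the *_from_dict constructors. Validation is performed structurally by the constructors themselves; this file documents the contract.",
  "$defs": {
    "stimulus": {
      "type": "object",
      "required": ["type", "params"],
      "properties": {
        "type": {"enum": ["sinusoid", "step", "square", "ramp"]},
        "params": {
          "oneOf": [
            {
              "type": "object",
              "required": ["mean_pressure", "amplitude", "angular_frequency"],
              "properties": {
                "mean_pressure": {"type": "number"},
                "amplitude": {"type": "number", "minimum": 0},
                "angular_frequency": {"type": "number", "exclusiveMinimum": 0},
                "phase": {"type": "number"}
              }
            },
            {
              "type": "object",
              "required": ["p_base", "p_target", "onset"],
              "properties": {
                "p_base": {"type": "number"},
                "p_target": {"type": "number"},
                "onset": {"type": "number"},
                "steepness": {"type": "number", "exclusiveMinimum": 0}
              }
            },
            {
              "type": "object",
              "required": ["p_base", "p_up", "t_up", "t_down"],
              "properties": {
                "p_base": {"type": "number"},
                "p_up": {"type": "number"},
                "t_up": {"type": "number"},
                "t_down": {"type": "number"},
                "steepness_up": {"type": "number", "exclusiveMinimum": 0},
                "steepness_down": {"type": "number", "exclusiveMinimum": 0}
              }
            },
            {
              "type": "object",
              "required": ["p_start", "p_end", "t_start", "t_end"],
              "properties": {
                "p_start": {"type": "number"},
                "p_end": {"type": "number"},
                "t_start": {"type": "number"},
                "t_end": {"type": "number"},
                "symmetric_descend": {"type": "boolean"}
              }
            }
          ]
        }
      }
    },
    "wall": {
      "type": "object",
      "required": ["type", "params"],
      "properties": {
        "type": {"enum": ["linear", "nonlinear", "sls"]},
        "params": {"type": "object"}
      }
    },
    "chain": {
      "type": "object",
      "required": ["alpha", "beta"],
      "properties": {
        "n": {"enum": [1, 2, 3]},
        "alpha": {"type": "array", "items": {"type": "number", "exclusiveMinimum": 0}, "minItems": 1, "maxItems": 3},
        "beta": {"type": "array", "items": {"type": "number", "exclusiveMinimum": 0}, "minItems": 1, "maxItems": 3}
      }
    },
    "neuron": {
      "type": "object",
      "required": ["type", "params"],
      "properties": {
        "type": {"enum": ["linear", "integrate_fire"]},
        "params": {"type": "object"}
      }
    }
  },
  "type": "object",
  "properties": {
    "wall": {"$ref": "#/$defs/wall"},
    "chain": {"$ref": "#/$defs/chain"},
    "neuron": {"$ref": "#/$defs/neuron"},
    "stimulus": {"$ref": "#/$defs/stimulus"}
  }
}
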