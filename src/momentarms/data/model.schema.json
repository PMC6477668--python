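{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Hinge-jointed limb model definition",
  "description": "Body segments, hinge joints and polyline muscle paths. All lengths in mm, all angles in degrees, axis vectors as 3-element arrays in the parent body's frame.",
  "type": "object",
  "required": ["bodies", "joints", "muscles"],
  "properties": {
    "bodies": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["name"],
        "properties": {
          "name": {"type": "string", "minLength": 1},
          "parent_joint": {"type": "string"},
          "reference_length": {"type": "number", "exclusiveMinimum": 0}
        }
      }
    },
    "joints": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["name", "parent_body", "child_body", "center", "axis"],
        "properties": {
          "name": {"type": "string", "minLength": 1},
          "parent_body": {"type": "string"},
          "child_body": {"type": "string"},
          "center": {"type": "array", "items": {"type": "number"}, "minItems": 3, "maxItems": 3},
          "axis": {"type": "array", "items": {"type": "number"}, "minItems": 3, "maxItems": 3},
          "angle_limits": {"type": "array", "items": {"type": "number"}, "minItems": 2, "maxItems": 2},
          "zero_pose_note": {"type": "string"}
        }
      }
    },
    "muscles": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["name", "attachments"],
        "properties": {
          "name": {"type": "string", "minLength": 1},
          "group": {"type": "string"},
          "attachments": {
            "type": "array",
            "minItems": 2,
            "items": {
              "type": "object",
              "required": ["body", "xyz"],
              "properties": {
                "body": {"type": "string"},
                "xyz": {"type": "array", "items": {"type": "number"}, "minItems": 3, "maxItems": 3},
                "label": {"type": "string"}
              }
            }
          }
        }
      }
    }
  }
}
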