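{
  "type": "object",
  "required": [
    "psyctrl_version",
    "config",
    "n_participants",
    "n_items",
    "excluded",
    "effects",
    "associations",
    "prediction_accuracy",
    "warnings"
  ],
  "properties": {
    "psyctrl_version": {"type": "string"},
    "config": {"type": "object"},
    "n_participants": {"type": "integer"},
    "n_items": {"type": "integer"},
    "excluded": {"type": "array"},
    "effects": {
      "type": "object",
      "required": ["participants", "items"],
      "properties": {
        "participants": {"type": "object", "required": ["sensitivity", "specificity"]},
        "items": {"type": "object", "required": ["sensitivity", "specificity"]}
      }
    },
    "associations": {
      "type": "array",
      "items": {
        "type": "object",
        "required": [
          "pairing",
          "provenance",
          "mean_tau",
          "std_tau",
          "group_p",
          "n_significant",
          "n_participants",
          "n_excluded",
          "alpha"
        ]
      }
    },
    "prediction_accuracy": {"type": "object"},
    "warnings": {"type": "array"}
  }
}
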