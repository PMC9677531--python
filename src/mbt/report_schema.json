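{
  "type": "object",
  "required": ["config_hash", "software_version", "seed", "plan", "dosimetry", "quantification", "survival", "stage_log"],
  "properties": {
    "config_hash": {"type": "string"},
    "software_version": {"type": "string"},
    "seed": {"type": "integer"},
    "plan": {
      "type": "object",
      "required": ["injections", "coverage", "feasible"],
      "properties": {
        "injections": {"type": "array"},
        "coverage": {"type": "number"},
        "feasible": {"type": "boolean"}
      }
    },
    "dosimetry": {
      "type": "object",
      "required": ["v60_pct", "v100_pct", "d95_gy", "v_constraint_pct"],
      "properties": {
        "v60_pct": {"type": "number"},
        "v100_pct": {"type": "number"},
        "d95_gy": {"type": "number"},
        "v_constraint_pct": {"type": "number"},
        "healthy_v10_pct": {"type": "number"}
      }
    },
    "quantification": {
      "type": "object",
      "required": ["injected_mbq", "recovered_mbq", "recovery_ratio"],
      "properties": {
        "injected_mbq": {"type": "number"},
        "recovered_mbq": {"type": "number"},
        "recovery_ratio": {"type": "number"},
        "calibration_slope": {"type": "number"},
        "calibration_intercept": {"type": "number"}
      }
    },
    "survival": {
      "type": "object",
      "required": ["mean_treated_days", "mean_untreated_days", "logrank_p"],
      "properties": {
        "mean_treated_days": {"type": "number"},
        "mean_untreated_days": {"type": "number"},
        "logrank_p": {"type": "number"},
        "logrank_statistic": {"type": "number"}
      }
    },
    "stage_log": {"type": "array"}
  }
}
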