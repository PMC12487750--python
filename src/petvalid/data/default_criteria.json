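{
  "calibration_tolerance": {
    "tier1": {"F-18": 0.05, "Ga-68": 0.05, "default": 0.10},
    "tier2": {"default": 0.10}
  },
  "frequency": {
    "calibration": {"F-18": "quarterly", "Ga-68": "quarterly", "default": "annual"},
    "recovery": {"default": "annual"}
  },
  "crc_limits": [
    {"diameter_mm": 10, "min": 0.45, "max": 0.86},
    {"diameter_mm": 13, "min": 0.83, "max": 1.25},
    {"diameter_mm": 17, "min": 1.00, "max": 1.43},
    {"diameter_mm": 22, "min": 1.01, "max": 1.37},
    {"diameter_mm": 28, "min": 1.01, "max": 1.30},
    {"diameter_mm": 37, "min": 1.06, "max": 1.33}
  ],
  "contrast": 8,
  "metric": "max",
  "revalidation_triggers": [
    "software_update",
    "major_service",
    "ge68_phantom_replacement",
    "calibrator_service"
  ]
}
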