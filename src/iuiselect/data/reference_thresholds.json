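[
  {"parameter": "male_age", "direction": "upper", "cutoff": 41.0, "source_period": "discovery", "status": "validated", "source_group": "pregnancy"},
  {"parameter": "ejaculate_concentration", "direction": "lower", "cutoff": 10.36, "source_period": "discovery", "status": "validated", "source_group": "pregnancy"},
  {"parameter": "ejaculate_total_count", "direction": "lower", "cutoff": 51.79, "source_period": "discovery", "status": "validated", "source_group": "pregnancy"},
  {"parameter": "ejaculate_alkaline_comet", "direction": "upper", "cutoff": 72.0, "source_period": "discovery", "status": "validated", "source_group": "pregnancy"},
  {"parameter": "swimup_immotile", "direction": "upper", "cutoff": 45.0, "source_period": "discovery", "status": "validated", "source_group": "pregnancy"},
  {"parameter": "swimup_alkaline_comet", "direction": "upper", "cutoff": 59.0, "source_period": "discovery", "status": "validated", "source_group": "pregnancy"},
  {"parameter": "swimup_neutral_comet", "direction": "upper", "cutoff": 65.0, "source_period": "validation", "status": "validated", "source_group": "pregnancy"},
  {"parameter": "female_bmi", "direction": "upper", "cutoff": 45.0, "source_period": "discovery", "status": "validated", "source_group": "no_pregnancy"},
  {"parameter": "infertility_duration", "direction": "upper", "cutoff": 84.0, "source_period": "validation", "status": "validated", "source_group": "no_pregnancy"},
  {"parameter": "lh", "direction": "upper", "cutoff": 27.28, "source_period": "discovery", "status": "validated", "source_group": "no_pregnancy"},
  {"parameter": "antral_follicle_count", "direction": "lower", "cutoff": 3.0, "source_period": "discovery", "status": "validated", "source_group": "no_pregnancy"}
]
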