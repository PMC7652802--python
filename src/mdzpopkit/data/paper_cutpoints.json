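{
  "parameter_name": "Qmet",
  "t_low": 16.4,
  "t_high": 41.8,
  "range_low": 4.82,
  "range_high": 88.9,
  "labels": ["inhibition", "no_modulation", "induction"],
  "training_accuracy": null
}
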