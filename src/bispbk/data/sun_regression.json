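{
  "comment": "Caco-2 Papp to human jejunal Peff scaling, 'all drugs' regression: log10(Peff / 1e-4 cm/s) = slope * log10(Papp / 1e-6 cm/s) + intercept",
  "slope": 0.4926,
  "intercept": -0.1454,
  "papp_unit": "1e-6 cm/s",
  "peff_unit": "1e-4 cm/s"
}
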