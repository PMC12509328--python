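# SYNTHETIC placeholder plasma unbound fractions (unitless).
chemical,fu_parent,fu_glucuronide
BPA,0.055,0.80
BPAF,0.030,0.75
BPB,0.040,0.78
BPE,0.070,0.82
BPF,0.080,0.85
BPM,0.010,0.70
BPS,0.120,0.90
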