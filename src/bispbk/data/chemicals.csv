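name,mw_parent,mw_glucuronide,logp,pka
BPA,228.29,404.41,3.32,9.6
BPAF,336.23,512.35,4.47,9.2
BPB,242.32,418.44,3.85,9.7
BPE,214.26,390.38,2.97,9.8
BPF,200.23,376.35,2.91,9.9
BPM,346.47,522.59,6.25,9.9
BPS,250.27,426.39,1.65,8.2
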