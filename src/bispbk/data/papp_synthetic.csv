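# SYNTHETIC placeholder Caco-2 apparent permeabilities (1e-6 cm/s).
# In vitro entries exist only for BPA, BPF, BPS; QSAR-K / QSAR-L predictions
# cover all seven bisphenols. Values are representative, not measured data.
chemical,source,papp_1e6_cm_s
BPA,in_vitro,42
BPA,QSAR-K,38
BPA,QSAR-L,35
BPAF,QSAR-K,30
BPAF,QSAR-L,25
BPB,QSAR-K,40
BPB,QSAR-L,36
BPE,QSAR-K,36
BPE,QSAR-L,33
BPF,in_vitro,38
BPF,QSAR-K,36
BPF,QSAR-L,30
BPM,QSAR-K,28
BPM,QSAR-L,12
BPS,in_vitro,20
BPS,QSAR-K,8
BPS,QSAR-L,9
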