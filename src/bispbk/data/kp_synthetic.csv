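# SYNTHETIC placeholder tissue:blood partition coefficients (unitless),
# loosely ordered by lipophilicity; glucuronide Kp values are low and polar.
# breast entries are intentionally absent: derived as 0.245 * adipose Kp.
chemical,organ,kp_parent,kp_glucuronide
BPA,liver,1.5,0.5
BPA,kidney,1.2,0.6
BPA,gut,1.4,0.4
BPA,slow,1.1,0.3
BPA,rapid,1.3,0.4
BPA,thyroid,1.2,0.3
BPA,testes,0.9,0.3
BPA,adipose,6.0,0.1
BPAF,liver,2.5,0.5
BPAF,kidney,2.0,0.6
BPAF,gut,2.2,0.4
BPAF,slow,1.8,0.3
BPAF,rapid,2.0,0.4
BPAF,thyroid,4.5,0.3
BPAF,testes,1.4,0.3
BPAF,adipose,15.0,0.1
BPB,liver,2.0,0.5
BPB,kidney,1.6,0.6
BPB,gut,1.8,0.4
BPB,slow,1.4,0.3
BPB,rapid,1.6,0.4
BPB,thyroid,1.6,0.3
BPB,testes,1.1,0.3
BPB,adipose,10.0,0.1
BPE,liver,1.2,0.5
BPE,kidney,1.0,0.6
BPE,gut,1.1,0.4
BPE,slow,0.9,0.3
BPE,rapid,1.0,0.4
BPE,thyroid,1.0,0.3
BPE,testes,0.8,0.3
BPE,adipose,4.5,0.1
BPF,liver,1.1,0.5
BPF,kidney,0.95,0.6
BPF,gut,1.0,0.4
BPF,slow,0.85,0.3
BPF,rapid,0.95,0.4
BPF,thyroid,1.0,0.3
BPF,testes,0.8,0.3
BPF,adipose,4.0,0.1
BPM,liver,4.0,0.5
BPM,kidney,3.0,0.6
BPM,gut,3.5,0.4
BPM,slow,2.8,0.3
BPM,rapid,3.0,0.4
BPM,thyroid,12.0,0.3
BPM,testes,4.0,0.3
BPM,adipose,40.0,0.1
BPS,liver,0.7,0.5
BPS,kidney,0.6,0.6
BPS,gut,0.65,0.4
BPS,slow,0.55,0.3
BPS,rapid,0.6,0.4
BPS,thyroid,0.9,0.3
BPS,testes,0.6,0.3
BPS,adipose,1.2,0.1
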