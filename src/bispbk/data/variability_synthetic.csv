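# SYNTHETIC placeholder variability table for sensitivity ranges and Monte
# Carlo distributions: parameter path, distribution family, coefficient of
# variation. Ranges for screening span ~±2 SD around the baseline value.
parameter,family,cv
bw,normal,0.15
cardiac_output,normal,0.15
ehcr,normal,0.10
vmax,lognormal,0.30
km,lognormal,0.30
vol_frac.liver,normal,0.15
flow_frac.liver,normal,0.15
gest,lognormal,0.30
sfg,lognormal,0.25
ka,lognormal,0.25
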