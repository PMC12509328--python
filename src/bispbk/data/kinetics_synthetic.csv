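# SYNTHETIC placeholder glucuronidation kinetic constants used to generate
# substrate-depletion fixtures and to parameterize demo simulations.
# vmax in nmol/min/mg protein, km and ki in uM. Ordering (BPB fastest,
# BPS slowest) follows the qualitative ranking of hepatic glucuronidation.
chemical,system,model,vmax_nmol_min_mg,km_uM,ki_uM
BPA,human_S9,MM,5.0,45,
BPB,human_S9,MM,6.0,40,
BPE,human_S9,MM,2.5,55,
BPM,human_S9,MM,4.5,35,
BPS,human_microsome,MM,0.6,70,
BPF,human_microsome,MM,2.0,60,
BPAF,human_microsome,substrate_inhibition,1.5,30,400
BPA,rat_S9,MM,4.0,50,
BPAF,rat_S9,MM,1.8,40,
BPF,rat_S9,MM,2.2,55,
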