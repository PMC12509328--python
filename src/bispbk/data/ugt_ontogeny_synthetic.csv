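# SYNTHETIC placeholder UGT2B15 protein abundances (pmol/mg microsomal
# protein) by age class; child and toddler models both map to early_childhood.
age_class,abundance_pmol_mg
adult,61.0
early_childhood,26.0
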