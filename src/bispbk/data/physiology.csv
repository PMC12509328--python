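# Standard reference physiologies (ICRP-style). Volume fractions (vf_*) are
# fractions of body weight (density 1 kg/L assumed); flow fractions (ff_*) are
# fractions of cardiac output and sum to 1 over perfused compartments.
# gonad = testes (male models) or breasts (woman model); absent in the rat.
label,species,sex,bw_kg,height_cm,cardiac_output_L_h,gest_h,gfr_L_h,bile_flow_L_day,intestinal_radius_cm,ugt_class,vf_liver,vf_kidney,vf_gut,vf_blood,vf_slow,vf_rapid,vf_thyroid,vf_gonad,ff_liver,ff_gut,ff_kidney,ff_slow,ff_rapid,ff_thyroid,ff_gonad
man,human,male,73,176,390,0.4,7.5,0.7,1.75,adult,0.0247,0.0043,0.017,0.077,0.52,0.10,0.00027,0.00048,0.065,0.16,0.19,0.2795,0.29,0.015,0.0005
woman,human,female,60,163,354,0.4,6.6,0.7,1.6,adult,0.0233,0.0046,0.017,0.071,0.55,0.10,0.00028,0.0087,0.065,0.17,0.17,0.30,0.275,0.015,0.005
child,human,male,32,138,240,0.4,4.3,0.45,1.2,early_childhood,0.031,0.0048,0.019,0.075,0.50,0.12,0.00025,0.00009,0.065,0.16,0.17,0.29,0.30,0.0145,0.0005
toddler,human,male,12,88,125,0.4,1.7,0.2,0.9,early_childhood,0.033,0.005,0.02,0.08,0.48,0.13,0.0002,0.0001,0.065,0.155,0.165,0.30,0.30,0.0145,0.0005
rat,rat,male,0.25,20,5.0,0.25,0.078,0.024,0.18,adult,0.0366,0.0073,0.027,0.074,0.63,0.075,0,0,0.021,0.153,0.141,0.385,0.30,0,0
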