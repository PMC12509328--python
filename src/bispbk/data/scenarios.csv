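# Oral exposure scenarios. "all" = each of the seven bisphenols.
# Repeated dosing events occur at t = 0,6,12,24,30,36,48,56,60,72,78,84 h.
scenario,purpose,model,chemical,dose,dose_unit,schedule,duration_h
1,ehc_determination,rat,BPAF,340,mg_per_kg,single,48
2,ehc_determination,rat,BPF,200,mg_per_kg,single,48
3,model_evaluation,man,BPA,30,ug_per_kg,single,48
4,model_evaluation,man,BPS,8.1,ug_per_kg,single,48
5,internal_exposure,man,all,336,ng_per_kg,single,48
6,internal_exposure,woman,all,389,ng_per_kg,single,48
7,internal_exposure,child,all,818,ng_per_kg,single,48
8,internal_exposure,toddler,all,869,ng_per_kg,single,48
9,internal_exposure,man,all,112,ng_per_kg,repeated,96
10,internal_exposure,woman,all,130,ng_per_kg,repeated,96
11,internal_exposure,child,all,273,ng_per_kg,repeated,96
12,internal_exposure,toddler,all,290,ng_per_kg,repeated,96
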