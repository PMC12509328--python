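# In vivo and model-predicted blood toxicokinetic metrics for oral BPA
# (30 ug/kg bw, adult men) and BPS (8.75 ug/kg bw, adults) used for the
# 2-fold model evaluation. cmax in nM, tmax in h, auc in nM*day.
species,chemical,analyte,metric,observed,obs_low,obs_high,predicted,pred_low,pred_high
human,BPA,parent,cmax,0.43,0.3,0.7,0.27,0.15,0.47
human,BPA,glucuronide,cmax,286,173,386,228,168,297
human,BPS,parent,cmax,8.79,6.07,11.79,14.1,9.04,21.20
human,BPS,glucuronide,cmax,10.53,7.77,14.2,29.2,18.6,42.8
human,BPA,parent,tmax,1.6,0.5,2.2,0.70,0.61,0.93
human,BPA,glucuronide,tmax,1.2,0.8,2.2,1.16,1.00,1.31
human,BPS,parent,tmax,0.5,0.25,0.5,2.15,1.9,2.3
human,BPS,glucuronide,tmax,1.0,1.0,1.0,1.0,0.99,1.25
human,BPA,parent,auc,2.5,1.4,5.7,3.97,2.38,6.64
human,BPA,glucuronide,auc,680,571,1210,1036,710,1511
human,BPS,parent,auc,40,,,163,100,264
human,BPS,glucuronide,auc,78.7,54,103,191.3,125,284
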