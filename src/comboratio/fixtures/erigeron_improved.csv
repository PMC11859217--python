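time_h,conc_Bre_mean,conc_Bre_sd,conc_Scu_mean,conc_Scu_sd,conc_His_mean,conc_His_sd,n_effective,n_total,inhibition_pct
0.25,15.47,0.78,38.78,3.34,5.902,0.66,26,120,21.6
0.5,30.06,2.67,35.29,2.78,7.06,0.78,70,180,38.7
1,21.65,2.09,22.14,2.66,21.08,1.96,74,109,68.1
2,34.54,3.77,49.70,5.79,17.55,1.88,129,177,72.7
4,18.81,1.87,68.05,3.47,26.80,3.34,158,180,87.8
8,13.77,1.30,53.30,6.11,10.15,1.30,63,174,36.1
24,3.92,0.39,7.54,0.86,15.76,0.81,40,153,26.3
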