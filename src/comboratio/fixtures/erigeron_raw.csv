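time_h,conc_Bre_mean,conc_Bre_sd,conc_Scu_mean,conc_Scu_sd,conc_His_mean,conc_His_sd,n_effective,n_total,inhibition_pct
0.25,28.11,8.38,53.00,18.60,20.74,10.90,1,6,17
0.5,71.09,24.29,80.40,18.42,22.82,10.03,2,6,33
1,50.18,15.79,50.09,21.87,38.77,13.35,7,11,63
2,94.34,27.57,149.30,59.10,37.93,17.63,4,6,67
4,33.98,15.44,263.45,56.68,52.01,18.72,5,6,83
8,25.83,12.53,84.31,54.39,29.16,13.90,3,10,30
24,10.00,3.98,11.63,4.09,23.90,15.25,1,5,20
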