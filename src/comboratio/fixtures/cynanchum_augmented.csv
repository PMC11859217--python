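time_h,conc_M1_mean,conc_M1_sd,conc_M2_mean,conc_M2_sd,conc_PHB_mean,conc_PHB_sd,n_effective,n_total,inhibition_pct
0.17,5.10,3.50,0.45,0.48,3.13,1.30,11,94,11.7
0.5,5.50,2.50,0.50,0.35,3.33,1.01,36,96,37
1,4.70,0.85,0.35,0.33,2.33,1.91,67,80,84
1.5,4.00,1.70,0.37,0.35,2.56,1.33,83,133,62.5
4,3.60,1.15,0.40,0.38,3.11,0.89,87,122,71
7,3.40,2.40,0.37,0.32,1.83,0.76,77,101,77
12,0.30,0.25,0.32,0.33,2.33,0.40,59,79,75
24,0.32,0.09,0.02,0.01,0.34,0.18,46,85,54
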