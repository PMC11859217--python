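time_h,conc_M1_mean,conc_M1_sd,conc_M2_mean,conc_M2_sd,conc_PHB_mean,conc_PHB_sd,n_effective,n_total,inhibition_pct
0.17,2.24,1.55,0.22,0.23,1.68,0.67,15,96,16
0.5,3.70,2.03,0.18,0.10,1.51,0.36,39,96,41
1,3.67,1.13,0.23,0.08,1.79,2.81,71,80,89
1.5,1.38,0.64,0.23,0.21,0.97,0.47,90,133,68
4,1.11,0.34,0.19,0.18,1.13,0.32,93,121,76
7,0.98,0.67,0.22,0.04,0.80,0.32,83,101,82
12,0.86,0.52,0.02,0.04,1.10,0.25,63,96,80
24,0.35,0.52,0.01,0.04,0.34,0.39,50,85,59
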