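time_h,conc_M1_mean,conc_M1_sd,conc_M2_mean,conc_M2_sd,conc_PHB_mean,conc_PHB_sd,n_effective,n_total,inhibition_pct
0.17,5.37,5.07,0.48,0.66,3.38,1.80,1,6,17
0.5,5.92,3.43,0.28,0.22,3.32,1.18,2,6,33
1,5.11,1.90,0.44,0.34,3.40,6.56,4,5,80
1.5,4.02,1.88,0.33,0.39,3.49,2.00,5,8,63
4,3.65,1.35,0.28,0.35,2.96,1.05,5,7,71
7,3.39,3.06,0.03,0.05,1.75,1.02,5,7,71
12,3.17,1.82,0.03,0.01,1.70,0.57,4,5,80
24,0.34,0.14,0.00,0.00,0.30,0.27,3,6,50
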