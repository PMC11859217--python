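time_h,conc_M1_mean,conc_M1_sd,conc_M2_mean,conc_M2_sd,conc_PHB_mean,conc_PHB_sd,inhibition_pct,combination_index
0.17,2.24,1.55,0.22,0.23,1.68,0.67,16.7,12.0210
0.5,3.70,2.03,0.18,0.10,1.51,0.36,41,1.74799
1,3.67,1.13,0.23,0.08,1.79,2.81,89,0.03249
1.5,1.38,0.64,0.23,0.21,0.97,0.47,67.5,0.20925
4,1.11,0.34,0.19,0.18,1.13,0.32,76,0.10462
7,0.98,0.67,0.22,0.04,0.80,0.32,82,0.02495
12,0.86,0.52,0.02,0.04,1.10,0.25,80,0.04890
24,0.35,0.52,0.01,0.04,0.34,0.39,59,0.02729
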