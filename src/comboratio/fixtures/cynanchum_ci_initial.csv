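time_h,conc_M1_mean,conc_M1_sd,conc_M2_mean,conc_M2_sd,conc_PHB_mean,conc_PHB_sd,inhibition_pct,combination_index
0.17,5.10,3.50,0.45,0.48,3.13,1.30,11.7,48.0574
0.5,5.50,2.50,0.50,0.35,3.33,1.01,37,10.8582
1,4.70,0.85,0.35,0.33,2.33,1.91,84,0.91279
1.5,4.00,1.70,0.37,0.35,2.56,1.33,62.5,0.98306
4,3.60,1.15,0.40,0.38,3.11,0.89,71,0.46805
7,3.40,2.40,0.37,0.32,1.83,0.76,77,0.19855
12,0.30,0.25,0.32,0.33,2.33,0.40,75,0.07089
24,0.32,0.09,0.02,0.01,0.34,0.18,54,0.023674
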