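time_h,conc_Bre_mean,conc_Bre_sd,conc_Scu_mean,conc_Scu_sd,conc_His_mean,conc_His_sd,n_effective,n_total,inhibition_pct
0.25,29.38,6.49,52.22,14.22,21.76,8.49,20,120,16.7
0.5,65.56,22.42,79.62,16.59,24.38,7.69,60,180,33.3
1,53.09,15.36,59.09,20.92,35.96,10.97,69,109,63.3
2,89.20,21.17,141.02,43.56,36.72,13.23,119,177,67.2
4,32.30,11.92,266.54,46.20,50.89,12.78,150,180,83.3
8,27.37,10.62,83.55,44.07,31.26,14.21,54,174,31
24,10.31,3.33,11.37,3.41,21.69,12.67,33,153,21.5
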