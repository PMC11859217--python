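time_h,conc_PHB_mean,conc_PHB_sd,n_effective,n_total,inhibition_pct
0.17,2.054,0.261,1,4,25
0.5,2.066,0.797,2,6,33
1,3.321,1.422,4,5,80
1.5,2.959,0.725,4,6,67
4,2.973,1.112,4,6,67
7,1.751,0.311,4,6,67
12,0.862,0.457,2,4,50
24,0.11,0.07,1,5,20
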