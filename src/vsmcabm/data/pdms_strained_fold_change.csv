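strain_label,eps_lo,eps_hi,time_h,observed_mean,observed_sd,model_mean
4-6%,0.04,0.06,24,1.22,0.19,1.44
4-6%,0.04,0.06,72,1.34,0.95,1.37
2-8%,0.02,0.08,24,0.99,0.29,1.04
2-8%,0.02,0.08,72,0.44,0.15,1.08
0-10%,0.00,0.10,24,0.80,0.14,0.87
0-10%,0.00,0.10,72,0.939,0.12,0.83
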