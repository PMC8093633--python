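initial_density,observed_mean,observed_sd,model_mean
305.21,682.81,166.21,516.86
798.74,1375.57,810.3,1339.00
457.92,746.11,20.95,763.38
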