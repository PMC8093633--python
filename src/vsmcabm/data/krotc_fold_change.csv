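k_rot_c,model_fold_change_72h
0,0.88
0.0005,0.92
0.001,0.88
0.01,0.91
0.05,1.03
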