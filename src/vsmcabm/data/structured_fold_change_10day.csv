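source,kappa,perpendicular_mean,perpendicular_sd,parallel_mean,parallel_sd
experiment,,1.23,1.714,0.458,0.035
model,100,1.72,,0.19,
model,8,1.28,,0.21,
model,5,1.11,,0.22,
model,2,0.72,,0.48,
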