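subject,n_targets,fixation_combo,stim_s,accuracy
S1,160,right+down+left+up,0.25,0.96875
S3,80,right+left,0.2,0.9375
S4,80,down+up,0.25,0.91
S5,120,right+left+up,0.2,0.8867
S7,80,down+up,0.2,0.9525
S10,120,right+left+up,0.2,0.8267
S11,80,down+up,0.2,0.875
S12,80,right+left,0.2,0.9175
S14,80,down+up,0.3,0.9475
S15,160,right+down+left+up,0.25,0.965
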