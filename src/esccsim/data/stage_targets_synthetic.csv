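kind,label,age_lo,age_hi,value,n_eff
stage_proportion,stage1,15,99,12,1000
stage_proportion,stage2,15,99,32,1000
stage_proportion,stage3,15,99,38,1000
stage_proportion,stage4,15,99,18,1000
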