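eligible_age_hi: 69
eligible_age_lo: 40
followup: 10
name: cixian
onset_multiplier: 1.3
sensitivity: 0.96
specificity: 0.63
uptake: 0.486
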