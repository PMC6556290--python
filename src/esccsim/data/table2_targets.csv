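kind,label,age_lo,age_hi,value,n_eff
incidence,escc,30,34,3.4,100000
incidence,escc,35,39,12.4,100000
incidence,escc,40,44,42.4,100000
incidence,escc,45,49,93.1,100000
incidence,escc,50,54,238.7,100000
incidence,escc,55,59,475.8,100000
incidence,escc,60,64,519.6,100000
incidence,escc,65,69,636.8,100000
incidence,escc,70,74,878.9,100000
incidence,escc,75,79,925.1,100000
incidence,escc,80,84,1145.1,100000
incidence,escc,85,99,967.6,100000
prevalence,bch_md,40,44,13.1,1000
prevalence,bch_md,45,49,16.7,1000
prevalence,bch_md,50,54,21.1,1000
prevalence,bch_md,55,59,22.6,1000
prevalence,bch_md,60,64,25.8,1000
prevalence,bch_md,65,69,24.3,1000
prevalence,md,40,44,1.24,1000
prevalence,md,45,49,2.26,1000
prevalence,md,50,54,3.62,1000
prevalence,md,55,59,5.37,1000
prevalence,md,60,64,5.5,1000
prevalence,md,65,69,5.67,1000
prevalence,sd,40,44,0.34,1000
prevalence,sd,45,49,0.77,1000
prevalence,sd,50,54,1.71,1000
prevalence,sd,55,59,2.58,1000
prevalence,sd,60,64,2.64,1000
prevalence,sd,65,69,3.84,1000
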