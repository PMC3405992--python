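interval,genotype,d_with,d_without
I5a,wt,10.28,26.9
I5b,wt,5.96,17.88
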