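interval,genotype,PD,TT,NPD
I5a,wt,6746,4845,81
I5a,hei10-2,2662,461,4
I5b,wt,8818,2825,29
I5b,hei10-2,2794,331,2
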