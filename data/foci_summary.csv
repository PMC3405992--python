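group,stage,genotype,mean,sd,n
Col-0@early_zygotene,early_zygotene,Col-0,97,18,64
Col-0@zygotene_pachytene,zygotene_pachytene,Col-0,113,28,41
Ws-4@early_zygotene,early_zygotene,Ws-4,32,13,37
Ws-4@zygotene_pachytene,zygotene_pachytene,Ws-4,151,31,35
Col-0@late_pachytene,late_pachytene,Col-0,8.8,2.1,85
Ws-4@late_pachytene,late_pachytene,Ws-4,7.1,1.7,58
Col-0@diakinesis,diakinesis,Col-0,9.4,1.8,38
Ws-4@diakinesis,diakinesis,Ws-4,8.6,1.3,25
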