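group,background,mean,sd,n
hei10-1,Ws,0.62,0.75,92
spo11-1,Ws,0.5,0.7,30
msh4,Ws,0.91,0.95,64
mer3,Ws,2.12,1.09,42
hei10 spo11-1,Ws,0,0,89
hei10 msh4,Ws,0.7,0.85,96
hei10 mer3,Ws,0.69,0.89,134
hei10-2,Col,1.37,1.11,56
msh4,Col,1.29,0.96,79
hei10 msh4,Col,1.53,0.89,75
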