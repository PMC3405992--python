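group,background,mean,sd,n
Ws-4,Ws,7.4,1,38
hei10-1,Ws,0.62,0.75,92
hei10-3,Ws,0.68,0.77,54
hei10-4,Ws,0.74,0.83,65
hei10-5,Ws,0.54,0.79,72
Col-0,Col,9.2,1,55
hei10-2,Col,1.37,1.11,56
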