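component,eigenvalue,VC,CVC
1,2.862,47.706,47.706
2,2.251,37.524,85.231
3,0.595,9.915,95.146
4,0.198,3.295,98.44
5,0.081,1.351,99.791
6,0.013,0.209,100
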