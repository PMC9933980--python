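variable,Y1,Y2
SPAD,0.826,-0.482
SS,-0.106,0.927
MDA,0.638,0.732
CAT,-0.562,-0.724
POD,-0.818,0.231
SOD,0.881,-0.215
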