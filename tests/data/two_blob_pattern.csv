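0,0,0,0,0,0,0,0,0,0,0,0
0,0,0,0,0,0,0,0,0,0,0,0
0,0,0,0.644195925778,0.797076457923,0.644753057917,0,0,0,0,0,0
0,0,0,0.803469962232,1,0.804564439837,0,0,0,0,0,0
0,0,0,0.651597864776,0.80540584173,0.655719271629,0,0,0,0,0,0
0,0,0,0,0,0,0,0,0,0,0,0
0,0,0,0,0,0,0,0,0,0,0,0
0,0,0,0,0,0,0,0.533023231637,0.625584644882,0.523057993546,0,0
0,0,0,0,0,0,0,0.625467593585,0.740757256486,0.616677684356,0,0
0,0,0,0,0,0,0,0.523038133242,0.616676374203,0.515136535165,0,0
0,0,0,0,0,0,0,0,0,0,0,0
0,0,0,0,0,0,0,0,0,0,0,0
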