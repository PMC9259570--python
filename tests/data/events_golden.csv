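animal,segment,onset_s,peak_s,amplitude_pct
crab-01,pre,1.250,1.550,0.523457
crab-01,pos,7.000,7.200,1.25
crab-01,pos,102.350,103.000,0.02
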