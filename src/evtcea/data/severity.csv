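mrs,probability,source,assumed
0,0.10,assumed default (recurrent stroke severity distribution),true
1,0.15,assumed default (recurrent stroke severity distribution),true
2,0.15,assumed default (recurrent stroke severity distribution),true
3,0.20,assumed default (recurrent stroke severity distribution),true
4,0.25,assumed default (recurrent stroke severity distribution),true
5,0.15,assumed default (recurrent stroke severity distribution),true
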