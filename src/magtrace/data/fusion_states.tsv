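leaf	fused
Chloroflexus	0
JP3_7	0
Kouleothrix	1
CP2_42A	1
Roseiflexus	1
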