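(Dehalococcoidetes,(((Herpetosiphon,Kallotenue),(Chloroflexus,(Kouleothrix,Roseiflexus))),(Anaerolineae,((JP3_13,CP1_1M,CP2_2F),(CP2_20G,JP1_16,JP1_20,(JP1_8,CP2_42A)),(JP3_7,Roseilinea)))));
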