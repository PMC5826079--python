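(Chloroflexus,(JP3_7,(CP2_42A,(Kouleothrix,Roseiflexus))));
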