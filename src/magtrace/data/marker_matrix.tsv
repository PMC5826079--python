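bin_id	16S	RpoB	Type 2 reaction center	bc complex	ACIII	Rhodopsin	Denitrification	A-Family HCO	B-Family HCO	3HP	Calvin Cycle
CP1_1M	-	+	-	+	-	-	-	-	-	-	-
CP2_2F	-	+	-	-	-	+	-	-	-	-	-
CP2_20G	-	+	-	+	-	-	nirK	+	-	-	-
CP2_42A	-	+	+ (fused)	+	+	+	-	+ (two)	+	-	-
JP1_8	-	+	-	-	-	-	-	-	-	-	-
JP1_16	-	+	-	+	-	-	-	+	-	-	-
JP1_20	-	+	-	+	-	-	nirK, NOR	+ (three)	-	-	-
JP1_191	-	+	-	-	-	-	-	-	-	-	-
JP3_7	-	+	+ (unfused)	+	-	-	-	+	+	-	-
JP3_13	-	+	-	+	-	+	-	+ (two)	-	-	-
Kouleothrix_aurantiaca	+	+	+ (fused)	+	-	-	nirK	+	+	-	+
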