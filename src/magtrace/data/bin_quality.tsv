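bin_id	n_cds	completeness_pct	contamination_pct	strain_het_pct	source
CP1_1M	1182	42.28	1.81	50	Nakabusa Cone Pool 1
CP2_2F	1734	49.46	0	0	Nakabusa Cone Pool 2
CP2_20G	2678	78.54	3.55	33.33	Nakabusa Cone Pool 2
CP2_42A	2897	79.44	10.42	16.13	Nakabusa Cone Pool 2
JP1_8	1973	58.13	0.13	0	Jinata Pool 1
JP1_16	3238	95.15	17.31	0	Jinata Pool 1
JP1_20	2878	79.09	4.78	20	Jinata Pool 1
JP1_191	334	10.63	1.8	0	Jinata Pool 1
JP3_7	3078	87	12.85	7.32	Jinata Pool 3
JP3_13	3116	96.17	10.87	75	Jinata Pool 3
Kouleothrix_aurantiaca	8993	85	0	0	Isolate from wastewater sludge
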