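strain_code	plant	tissue	closest_match	match_accession	coverage_pct	identity_pct	own_accession
PT09	PT	root	Alternaria angustiovoidea	MH861939.1	100	100	ON677861
PT55	PT	leaf	Aspergillus chrysellus	OL711749.1	100	100	ON677904
PT56	PT	leaf	Aspergillus chrysellus	OL711749.1	100	99.8	ON677905
PP39	PP	root	Aspergillus floccosus	KP987086.1	100	100	ON677888
PT66	PT	tuber	Aspergillus fumigatus	NR121481.1	100	100	ON677914
PT60	PT	tuber	Aspergillus minisclerotigenes	OL711675.1	100	99.8	ON677908
PT78	PT	tuber	Aspergillus minisclerotigenes	OL711675.1	99	99.8	ON677926
PT84	PT	tuber	Aspergillus minisclerotigenes	OL711675.1	100	100	ON677931
PP45	PP	stem	Aspergillus sydowii	MH854859.1	100	100	ON677894
PP53	PP	tuber	Aspergillus sydowii	MH854859.1	100	100	ON677902
PP69	PP	leaf	Aspergillus sydowii	MH854859.1	99	99.5	ON677917
PT11	PT	tuber	Aspergillus sydowii	MH854859.1	100	98.5	ON677863
PT13	PT	tuber	Aspergillus sydowii	MH854859.1	100	98.5	ON677865
PT16	PT	leaf	Aspergillus tubingensis	NR131293.1	100	99.8	ON677868
PP42	PP	tuber	Bjerkandera adusta	MH857085.1	100	99.5	ON677891
PP43	PP	leaf	Bjerkandera adusta	MH857085.1	100	99.5	ON677892
PT30	PT	tuber	Bjerkandera adusta	MH857085.1	100	99.5	ON677875
PT67	PT	tuber	Bjerkandera adusta	MH857085.1	99	99.6	ON677915
PT80	PT	leaf	Bjerkandera adusta	MH857085.1	100	99.5	ON677927
PP52	PP	leaf	Cercospora musigena	NR147294.1	100	100	ON677901
PP73	PP	stem	Cladosporium halotolerans	MH864551.1	100	100	ON677921
PP75	PP	tuber	Cladosporium halotolerans	MH864551.1	100	100	ON677923
PT77	PT	tuber	Cladosporium halotolerans	MH864551.1	100	99.6	ON677925
PT72	PT	tuber	Cladosporium tenuissimum	MH864840.1	100	100	ON677920
PT15	PT	tuber	Clonostachys rosea	MH864507.1	100	99.8	ON677867
PP49	PP	leaf	Colletotrichum incanum	NR160812.1	98	99.6	ON677898
PP50	PP	leaf	Colletotrichum tabaci	NR144804.1	98	100	ON677899
PP36	PP	stem	Daldinia eschscholtzii	KY610387.1	99	99.3	ON677885
PP48	PP	leaf	Fusarium duofalcatisporum	GQ505741.1	100	99.4	ON677897
PT02	PT	tuber	Fusarium duofalcatisporum	GQ505741.1	100	99.6	ON677856
PT03	PT	tuber	Fusarium duofalcatisporum	GQ505741.1	100	99.6	ON677857
PP41	PP	root	Fusarium falciforme	NR164424.1	96	99.8	ON677890
PT08	PT	root	Fusarium falciforme	NR164424.1	100	100	ON677860
PT25	PT	tuber	Fusarium nepalense	MH864615.1	99	100	ON677870
PP35	PP	stem	Fusarium oxysporum	MH865885.1	100	99.8	ON677884
PP37	PP	stem	Fusarium oxysporum	MH865885.1	100	99.8	ON677886
PP51	PP	leaf	Fusarium oxysporum	MH865885.1	99	98.8	ON677900
PT31-4	PT	stem	Fusarium oxysporum	MH865885.1	99	98.8	ON677879
PT59	PT	leaf	Fusarium oxysporum	MH865885.1	99	98.8	ON677907
PP46	PP	stem	Fusarium phaseoli	MH855640.1	100	98.9	ON677895
PP76	PP	tuber	Fusarium phaseoli	MH855640.1	100	98.9	ON677924
PT14	PT	tuber	Fusarium phaseoli	MH855640.1	100	99.1	ON677866
PT82	PT	tuber	Fusarium solani	NR163531.1	99	100	ON677929
PT83	PT	tuber	Fusarium solani	NR163531.1	100	100	ON677930
PP44	PP	tuber	Fusarium sp.	GU170647.1	99	100	ON677893
PT01	PT	tuber	Lecanicillium dimorphum	MH861964.1	100	99.7	ON677855
PT61	PT	tuber	Lecanicillium dimorphum	MH861964.1	99	99.7	ON677909
PT62	PT	tuber	Lecanicillium dimorphum	MH861964.1	99	99.7	ON677910
PP33	PP	root	Macrophomina phaseolina	MH864182.1	100	100	ON677882
PP47	PP	leaf	Meripilus giganteus	GQ355959.1	99	86.6	ON677896
PT07	PT	stem	Meyerozyma guilliermondii	MH545918.1	100	100	ON677859
PT17	PT	tuber	Meyerozyma guilliermondii	MH545918.1	100	100	ON677869
PP40	PP	tuber	Nigrospora pyriformis	NR153469.1	97	98.2	ON677889
PT04	PT	root	Paraleptosphaeria macrospora	MH862571.1	98	97.2	ON677858
PT29	PT	stem	Paraphaeosphaeria sp.	JX496120.1	100	98.1	ON677874
PT32	PT	stem	Paraphaeosphaeria sp.	JX496120.1	100	98.1	ON677881
PT63	PT	tuber	Penicillium asturianum	MH861321.1	100	100	ON677911
PP38	PP	root	Penicillium citrinum	MH856132.1	97	100	ON677887
PT58	PT	leaf	Penicillium citrinum	MH856132.1	99	100	ON677906
PT68	PT	leaf	Penicillium citrinum	MH856132.1	100	100	ON677916
PT26	PT	root	Penicillium philippinense	MH860600.1	99	98.4	ON677871
PT28	PT	root	Penicillium philippinense	MH860600.1	99	98.4	ON677873
PT54	PT	leaf	Penicillium ramusculum	MH857613.1	100	100	ON677903
PT12	PT	stem	Periconia byssoides	MH859902.1	100	99.3	ON677864
PT70	PT	stem	Phaeoisaria dalbergiae	NR175205.1	99	98.0	ON677918
PT74	PT	stem	Phaeoisaria dalbergiae	NR175205.1	100	97.8	ON677922
PT64	PT	tuber	Pseudoechria longicollis	NR145145.1	99	100	ON677912
PT10	PT	root	Schizophyllum commune	MH863418.1	100	100	ON677862
PT31	PT	stem	Talaromyces fusiformis	NR169911.1	100	100	ON677876
PT31-1	PT	stem	Talaromyces fusiformis	NR169911.1	100	100	ON677877
PT34	PT	tuber	Talaromyces fusiformis	NR169911.1	100	100	ON677883
PT65	PT	tuber	Talaromyces fusiformis	NR169911.1	100	100	ON677913
PT81	PT	tuber	Talaromyces fusiformis	NR169911.1	100	100	ON677928
PT31-3	PT	stem	Trametes hirsuta	MH860685.1	100	98.6	ON677878
PT31-5	PT	stem	Trametes hirsuta	MH860685.1	100	98.7	ON677880
PT27	PT	tuber	Trichoderma atroviride	AF456917.1	100	99.8	ON677872
PT71	PT	tuber	Zygosporium masonii	MH860771.1	100	99.6	ON677919
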