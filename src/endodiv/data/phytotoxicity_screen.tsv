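strain_code	rate_pct	sd_pct
PT01	100.0	0.0
PT02	NI
PT03	30.7	5.9
PT04	67.9	5.4
PT07	100.0	0.0
PT08	100.0	0.0
PT09	91.1	4.3
PT10	43.4	5.4
PT11	100.0	0.0
PT12	45.3	4.9
PT13	62.7	5.3
PT14	100.0	0.0
PT15	92.3	5.9
PT16	100.0	0.0
PT17	100.0	0.0
PT25	100.0	0.0
PT26	54.5	6.6
PT27	47.5	5.8
PT28	22.9	5.6
PT29	100.0	0.0
PT30	33.1	5.0
PT31	31.8	5.8
PT31-1	100.0	0.0
PT31-3	52.0	4.9
PT31-4	31.9	5.7
PT31-5	49.1	3.4
PT32	81.9	3.1
PT34	59.0	3.6
PT54	87.6	1.8
PT55	100.0	0.0
PT56	100.0	0.0
PT58	96.0	4.3
PT59	100.0	0.0
PT60	95.9	6.3
PT61	98.2	4.0
PT62	83.1	6.3
PT63	98.0	3.1
PT64	69.6	6.2
PT65	100.0	0.0
PT66	87.5	3.9
PT67	48.8	7.0
PT68	85.9	5.9
PT70	65.7	4.1
PT71	100.0	0.0
PT72	96.8	4.7
PT74	65.4	2.9
PT77	100.0	0.0
PT78	100.0	0.0
PT80	57.1	6.2
PT81	100.0	0.0
PT82	100.0	0.0
PT83	81.6	4.9
PT84	100.0	0.0
PP33	NI
PP35	44.1	6.8
PP36	13.4	2.9
PP37	100.0	0.0
PP38	72.0	5.8
PP39	100.0	0.0
PP40	93.8	6.0
PP41	34.5	4.6
PP42	95.5	4.8
PP43	65.7	5.6
PP44	35.0	5.4
PP45	NI
PP46	23.0	5.2
PP47	77.5	4.1
PP48	23.8	3.6
PP49	NI
PP50	15.2	4.4
PP51	85.2	3.7
PP52	13.4	3.3
PP53	NI
PP69	78.5	5.0
PP73	11.0	4.5
PP75	54.4	6.5
PP76	16.5	6.1
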