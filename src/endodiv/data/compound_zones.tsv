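sample_id	role	organism	mic_ug_ml	izd_mm	izd_sd_mm
compound_1	test	S_aureus	>100	NI
compound_1	test	M_tetragenus	>100	NI
compound_1	test	E_coli	>100	NI
compound_1	test	P_syringae_pv_actinidiae	>100	NI
compound_2	test	S_aureus	>100	NI
compound_2	test	M_tetragenus	>100	NI
compound_2	test	E_coli	>100	NI
compound_2	test	P_syringae_pv_actinidiae	>100	15.3	0.6
compound_3	test	S_aureus	>100	14.2	0.5
compound_3	test	M_tetragenus	>100	NI
compound_3	test	E_coli	>100	NI
compound_3	test	P_syringae_pv_actinidiae	>100	NI
compound_4	test	S_aureus	100	13.3	0.2
compound_4	test	M_tetragenus	>100	NI
compound_4	test	E_coli	>100	NI
compound_4	test	P_syringae_pv_actinidiae	25	16.2	0.6
compound_5	test	S_aureus	1.56	33.7	0.5
compound_5	test	M_tetragenus	3.13	31.0	0.8
compound_5	test	E_coli	1.56	36.0	0.8
compound_5	test	P_syringae_pv_actinidiae	1.56	40.2	0.7
compound_6	test	S_aureus	>100	NI
compound_6	test	M_tetragenus	>100	NI
compound_6	test	E_coli	>100	NI
compound_6	test	P_syringae_pv_actinidiae	>100	NI
compound_7	test	S_aureus	100	10.0	0.7
compound_7	test	M_tetragenus	>100	NI
compound_7	test	E_coli	>100	NI
compound_7	test	P_syringae_pv_actinidiae	6.25	26.0	0.5
gentamicin_sulfate	positive_control	S_aureus	1.56	21.7	0.6
gentamicin_sulfate	positive_control	M_tetragenus	3.13	25.7	0.9
gentamicin_sulfate	positive_control	E_coli	3.13	26.7	0.5
gentamicin_sulfate	positive_control	P_syringae_pv_actinidiae	6.25	26.0	1.0
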