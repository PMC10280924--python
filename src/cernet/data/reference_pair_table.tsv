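mirna_id	target_id	r	p	total_score	total_energy	max_score	max_energy	target_length	positions	mre_count
novel579_mature	circRNA_9564	-0.9072255	0.012511391	1885	-152.06	156	-17.28	76127	31397 66000 70644 43569 51686 64454 35374 51517 57810 64144 37643 44640 65080	13
novel339_mature	circRNA_9564	-0.9527047	0.00330237	1588	-202.81	164	-25.75	76127	63431 38521 4033 66980 70803 15099 34764 38924 12613 58194 73273	11
novel579_mature	circRNA_8401	-0.9430699	0.004769299	1336	-107.02	160	-19.15	25448	7523 121 4884 9022 10725 12785 7594 16888 4615	9
novel339_mature	circRNA_8312	-0.8283779	0.041653748	1327	-158.59	157	-24.75	33662	9101 15594 21235 14878 4987 9128 12990 11451 19182	9
novel130_mature	circRNA_8396	-0.8309213	0.040464655	712	-94.96	148	-23.49	44924	8036 11410 44039 16227 39995	5
novel62_star	circRNA_9690	-0.8276274	0.042007697	291	-35.27	151	-20.78	1793	527 441	2
novel62_star	circRNA_3497	-0.9782303	0.000705721	140	-20.62	140	-20.62	915	5	1
novel428_mature	circRNA_9874	-0.9387901	0.00550532	144	-23.33	144	-23.33	6583	1691	1
novel579_mature	circRNA_3257	-0.895058	0.015941393	143	-13.78	143	-13.78	758	366	1
novel34_mature>novel661_mature	circRNA_4140	-0.8588374	0.02848384	146	-20.52	146	-20.52	3145	1373	1
novel37_star	circRNA_9874	-0.8587394	0.028522444	145	-15.94	145	-15.94	6583	1797	1
novel14_mature	circRNA_3497	-0.816605	0.04736645	151	-23.54	151	-23.54	915	323	1
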