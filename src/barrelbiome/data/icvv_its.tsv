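taxon	group	Rioja_FML0	Rioja_BAN3	Rioja_BAN9	Rioja_BAN12	Rioja_BAO3	Rioja_BAO9	Rioja_BAO12	Rioja_BTN12	Rioja_BTO12
Coprinellus	a	0	0	0	0	0	0	178	0	0
Lophodermium	a	0	0	0	0	0	0	28	0	0
Malassezia	a	0	32	3	77	11	0	124	0	0
Torulaspora	a	2	0	1	79	27	0	71	1	0
Aspergillus	a	1	21	0	0	0	0	44	0	2
Saccharomyces	a	2273	1838	2298	2225	2168	2344	1936	2313	2321
Candida	b	0	99	21	0	0	7	0	0	0
Hanseniaspora	b	105	391	58	0	175	30	0	67	58
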