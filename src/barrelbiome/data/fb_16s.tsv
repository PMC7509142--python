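taxon	group	FB_BAO_0	FB_BAO_3	FB_BAO_6	FB_BAO_9	FB_BAN_0	FB_BAN_3	FB_BAN_6	FB_BAN_9	FB_BAN_12
Leuconostoc	a	0	1	0	0	0	27	0	0	0
Bradyrhizobium	a	0	604	0	1	1	0	52	0	0
Lactobacillus	a	0	1570	221	134	4	187	169	633	276
Corynebacterium	a	0	926	0	0	0	1	0	0	0
Delftia	a	3	1576	142	0	0	25	219	741	0
Staphylococcus	a	4	622	146	28	1	58	0	257	109
Streptococcus	a	0	0	134	0	0	100	233	501	145
Deinococcus	a	0	0	1518	1	0	0	0	0	0
Stenotrophomonas	a	2	1547	155	2	0	0	0	72	0
Pelomonas	a	21	4929	917	106	24	313	387	510	274
Acinetobacter	a	13	295	184	18	1	0	0	359	477
Thermicanus	a	0	863	0	0	0	0	0	0	0
Rothia	a	0	398	0	0	0	56	0	1	0
Cloacibacterium	a	0	3253	0	0	0	0	0	0	0
Vulcaniibacterium	a	0	0	197	19	0	0	0	0	0
Pseudomonas	a	4	1667	0	25	0	32	0	229	57
Bacteroides	a	0	13	0	0	0	0	0	0	0
Cutibacterium	a	0	1919	1183	75	3	594	824	1679	230
Glutamicibacter	a	0	400	3	0	0	0	0	3	0
Oenococcus	b	25553	9697	22808	493	30679	21541	27101	4305	20
Acidovorax	b	1032	3	0	0	0	0	0	1	1
Aquabacterium	b	474	1	0	0	0	0	0	138	0
Komagataeibacter	b	0	0	0	0	9	0	0	0	0
Lonsdalea	b	2	0	0	0	0	0	0	0	0
Acetobacter	b	3669	531	3207	29913	55	7870	1830	21385	29158
Candidatus Finniella	b	3	0	0	0	0	0	0	0	0
Gluconobacter	b	0	0	0	0	21	11	0	1	0
Flavobacterium	b	35	0	0	0	17	0	0	0	68
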