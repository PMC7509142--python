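taxon	group	Rioja_FML0	Rioja_BAN3	Rioja_BAN9	Rioja_BAN12	Rioja_BAO3	Rioja_BAO9	Rioja_BAO12	Rioja_BTN12	Rioja_BTO12
Oenococcus	a	87265	82877	67457	55563	97918	61883	45720	95026	94129
Acetobacter	a	5996	17848	21020	45646	2935	35985	55457	5893	6715
Lactobacillus	a	7796	494	20	4	380	26	30	295	364
Komagataeibacter	b	18	6	6000	10	8	2443	10	0	5
Gluconobacter	b	159	11	4653	13	1	821	25	27	27
Lactococcus	b	9	7	2093	7	1	85	1	2	3
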