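taxon	group	FB_BAO_0	FB_BAO_3	FB_BAO_6	FB_BAO_9	FB_BAN_0	FB_BAN_3	FB_BAN_6	FB_BAN_9	FB_BAN_12
Unidentified	a	1	0	1	1	1	1	0	2	0
Trametes	a	0	0	0	0	0	0	0	6	0
Debaryomyces	a	0	0	0	0	0	0	0	0	1
Hanseniaspora	a	6	0	13	1	11	10	32	63	0
Saccharomyces	a	2825	1720	2816	2663	2820	2821	2793	2761	2827
Aspergillus	b	0	0	0	114	0	0	0	0	0
Malassezia	b	0	1112	2	53	0	0	7	0	4
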