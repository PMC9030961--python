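row	SNP|Saliva;Blood	SNP|Saliva;Lesion	SNP|Saliva;Blood;Lesion	SNP|Lesion-Specific	INDEL|Saliva;Blood	INDEL|Saliva;Lesion	INDEL|Saliva;Blood;Lesion	INDEL|Lesion-Specific
missense	43	12	882	9	0	0	0	0
synonymous	29	10	925	5	0	0	0	0
unknown	1	9	52	4	1	21	22	2
stopgain	0	0	8	0	1	0	0	0
nonframeshift_insertion	0	0	0	0	0	6	3	13
nonframeshift_deletion	0	0	0	0	0	6	5	20
frameshift_insertion	0	0	0	0	2	6	5	5
frameshift_deletion	0	0	0	0	0	3	5	6
Total variants	73	31	1866	18	4	42	40	46
(Total Genes)	49	21	1261	12	3	37	38	34
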