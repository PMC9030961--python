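row	SNP|Saliva;Blood	SNP|Saliva;Lesion	SNP|Saliva;Blood;Lesion	SNP|Lesion-Specific	INDEL|Saliva;Blood	INDEL|Saliva;Lesion	INDEL|Saliva;Blood;Lesion	INDEL|Lesion-Specific
Intragenic	157	52	3199	611	38	202	238	750
exonic	73	31	1866	18	4	41	40	46
intronic	67	16	1082	556	31	138	180	624
exonic;splicing	0	0	1	0	0	1	0	0
splicing	0	0	8	0	1	6	9	2
UTR5	5	4	144	16	1	12	5	36
UTR3	12	1	98	21	1	4	4	42
UTR5;UTR3	0	0	0	0	0	0	0	0
intergenic	33	15	281	416	4	12	15	213
upstream;downstream	0	0	1	1	0	0	0	4
upstream	2	1	24	19	0	4	1	31
downstream	0	1	9	13	0	0	1	7
ncRNA_exonic	12	7	128	15	0	11	4	27
ncRNA_splicing	0	0	0	1	0	0	0	0
ncRNA_intronic	12	3	71	75	4	12	6	57
ncRNA_exonic;splicing	0	0	0	0	0	0	0	0
NA	0	0	163	0	0	0	0	0
Total variants	216	79	3876	1151	46	241	265	1089
(Total Genes)	142	54	2125	598	41	205	230	687
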