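# Genomic-disorder locus catalog (hg19, half-open coordinates).
# Region bounds are editorial: each is drawn around the disorder's
# critical region tightly enough that neighbouring loci on the same
# chromosome arm stay distinct (e.g. proximal vs distal 22q11.2,
# terminal vs REPD-REPP 8p23.1, distal 13q12.3 vs the 13q11q12.3
# duplication territory). causal_cnv_type restricts the syndromic-obesity
# causality flag to one CNV type where only that type is established.
# known_genomic_disorder=0 entries are carried for annotation only
# (single-gene disorders, not genomic-disorder regions).
locus_id	chrom	start	end	known_genomic_disorder	causal_for_syndromic_obesity	causal_cnv_type	description
1p36	chr1	0	12500000	1	1	del	1p36 deletion syndrome, terminal and interstitial critical regions
1p21.3	chr1	95500000	99900000	1	1	del	1p21.3 microdeletion (DPYD-MIR137)
1q21.1_distal	chr1	146000000	148000000	1	0	any	1q21.1 distal deletion/duplication (CHD1L-GJA5)
2p25.3	chr2	0	3500000	1	1	del	2p25.3 terminal deletion (MYT1L, TMEM18)
2q37	chr2	234800000	243199373	1	1	del	2q37 deletion syndrome (HDAC4)
6q16	chr6	98000000	102000000	1	1	del	6q16 deletion (SIM1, POU3F2)
7q11.23	chr7	72300000	75200000	1	0	any	Williams-Beuren region (ELN)
8p23_terminal	chr8	0	7900000	1	0	any	8p23 terminal deletion, distal to REPD
8p23.1	chr8	8000000	12000000	1	0	any	recurrent REPD-REPP 8p23.1 region (GATA4)
9p_terminal	chr9	0	15500000	1	0	any	9p deletion syndrome region
9q34.3	chr9	140500000	141213431	1	1	del	Kleefstra syndrome (EHMT1)
12p13.31	chr12	6900000	7000000	1	1	dup	GNB3 duplication of the recurrent t(8;12)(p23.1;p13.31)
13q12.3	chr13	31040000	33500000	1	0	any	13q12.3 microdeletion, distal critical segment
15q11.2	chr15	22700000	23100000	1	0	any	15q11.2 BP1-BP2 (NIPA1), reduced penetrance
16p13.11	chr16	14900000	16300000	1	0	any	16p13.11 deletion/duplication (NDE1), reduced penetrance
16p11.2_BP2_3	chr16	28820000	29050000	1	1	del	distal 16p11.2 220-kb deletion (SH2B1)
16p11.2_BP4_5	chr16	29580000	30200000	1	1	del	proximal 16p11.2 600-kb region, reduced penetrance
17p11.2	chr17	16600000	20500000	1	1	del	Smith-Magenis region (RAI1)
17q21.31	chr17	43700000	44300000	1	0	any	17q21.31 region (KANSL1)
19p13.2	chr19	13050000	13250000	1	0	any	19p13.2 duplication (NFIX)
19p13.12	chr19	15052889	15492848	1	0	any	19p13.12 deletion shared interval (NOTCH3)
22q11.2_proximal	chr22	18650000	21460000	1	0	any	DiGeorge/VCFS proximal 22q11.2 region (TBX1)
22q11.2_distal	chr22	21700000	23900000	1	0	any	distal 22q11.2 deletion region (MAPK1)
Xp22.13_CDKL5	chrX	18400000	18700000	0	0	any	CDKL5 single-gene region, annotation only
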