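patient_id	cnv_type	cytoband	chrom	start	end	size	origin	clinical_class	disorder_label	rearrangement_kind
P1	del	1p36.33	chr1	734595	1970865	1236270	Unk	pathogenic	1p36 terminal deletion	simple
P2	del	1p36.33	chr1	734595	2223317	1488722	Unk	pathogenic	1p36 terminal deletion, complex	complex_component
P2	dup	1p36.33p36.32	chr1	2225679	2694799	469120	--	pathogenic	1p36 terminal deletion, complex	complex_component
P3	del	1p36.33p36.32	chr1	794592	2377269	1582677	De novo	pathogenic	1p36 terminal deletion	simple
P4	del	1p36.33p36.32	chr1	734595	3531040	2796445	Unk	pathogenic	1p36 terminal deletion	simple
P5	del	1p36.31p36.22	chr1	6204969	9433118	3228149	Unk	pathogenic	1p36 interstitial deletion	simple
P6	del	1p22.1p21.2	chr1	93919217	99846176	5926959	De novo	pathogenic	1p21.3 deletion	simple
P7	del	1p21.3p13.3	chr1	95696444	107755879	12059435	Unk	pathogenic	1p21.3 deletion	simple
P8	dup	1q21.1	chr1	146074084	147828029	1753945	Unk	pathogenic	1q21.1 distal duplication	simple
P9	del	2p25.3	chr2	63452	3215593	3152141	De novo	pathogenic	2p25.3 terminal deletion	simple
P10	del	2q37.2q37.3	chr2	237220842	242995835	5774993	De novo	pathogenic	2q37 terminal deletion	simple
P11	del	2q37.2q37.3	chr2	236854160	242995835	6141675	Unk	pathogenic	2q37 terminal deletion	simple
P12	del	2q37.2q37.3	chr2	236944801	243014630	6069829	De novo	pathogenic	2q37 terminal deletion, complex	complex_component
P12	dup	2q37.1q37.2	chr2	235090417	236802930	1712513	--	pathogenic	2q37 terminal deletion, complex	complex_component
P13	del	2q37.1q37.3	chr2	234850276	243028335	8178059	Unk	pathogenic	2q37 terminal deletion, complex	complex_component
P13	dup	2q37.1	chr2	233867403	234794816	927413	--	pathogenic	2q37 terminal deletion, complex	complex_component
P14	del	2q37.3	chr2	240880562	242948060	2067498	Unk	pathogenic	Unbalanced translocation	unbalanced_translocation
P15	del	6q16.1q21	chr6	95836632	108010940	12174308	De novo	pathogenic	6q16 deletion	simple
P16	del	7q11.23	chr7	72420782	74985644	2564862	Unk	pathogenic	7q11.23 deletion	simple
P17	del	7q11.23	chr7	72437606	75053787	2616181	Unk	pathogenic	7q11.23 deletion	simple
P18	del	8p23.3p23.1	chr8	176464	7786759	7610295	De novo	pathogenic	Unbalanced translocation	unbalanced_translocation
P18	dup	12p13.33p13.31	chr12	204618	8309473	8104855	--	pathogenic	Unbalanced translocation	unbalanced_translocation
P19	dup	8p23.1	chr8	8054556	11985356	3930800	Not mat	pathogenic	8p23.1 duplication	simple
P19	dup	13q12.12	chr13	23706634	24910765	1204131	Not mat	uncertain	Uncertain	simple
P20	del	9p24.3p22.3	chr9	40910	14304973	14264063	De novo	pathogenic	9p terminal deletion	simple
P21	del	9p24.3p22.3	chr9	204149	15260439	15056290	De novo	pathogenic	9p terminal deletion	simple
P22	del	9p24.3p22.3	chr9	201149	8807593	8606444	Unk	pathogenic	9p terminal deletion	simple
P23	del	9q34.3	chr9	140665414	141018984	353570	De novo	pathogenic	9q34.3 deletion	simple
P24	del	13q12.3q13.1	chr13	29081250	33529310	4448060	De novo	pathogenic	13q12.3 deletion	simple
P25	del	15q11.2	chr15	22729423	23086969	357546	Unk	pathogenic	15q11.2 microdeletion	simple
P26	del	16p13.12p13.11	chr16	14780302	16400774	1620472	Pat	pathogenic	16p13.1 deletion	simple
P27	dup	16p13.12p13.11	chr16	14796004	16586941	1790937	Pat	pathogenic	16p13.1 duplication	simple
P28	del	16p11.2	chr16	28843754	29044850	201096	De novo	pathogenic	16p11.2 (BP 2-3) deletion	simple
P29	del	16p11.2	chr16	29592751	30197466	604715	Not mat	pathogenic	16p11.2 (BP 4-5) deletion	simple
P30	dup	16p11.2	chr16	29592751	30197466	604715	Pat	pathogenic	16p11.2 (BP 4-5) duplication	simple
P31	del	17p11.2	chr17	17006987	20171357	3164370	De novo	pathogenic	17p11.2 deletion	simple
P32	del	17p11.2	chr17	16757563	20395535	3637972	Not mat	pathogenic	17p11.2 deletion	simple
P33	del	17p11.2	chr17	16603145	20395535	3792390	De novo	pathogenic	17p11.2 deletion	simple
P34	del	17p11.2	chr17	16603145	20395535	3792390	Unk	pathogenic	17p11.2 deletion	simple
P35	del	17p11.2	chr17	16603145	20463399	3860254	De novo	pathogenic	17p11.2 deletion	simple
P36	dup	17q21.31q21.32	chr17	40993738	45166786	4173048	De novo	pathogenic	17q21.3 duplication	simple
P37	dup	19p13.2	chr19	12640509	13231703	591194	Unk	pathogenic	19p13.2 duplication	simple
P37	dup	9p22.1	chr9	19066513	19497724	431211	Unk	uncertain	Uncertain	simple
P38	del	19p13.12	chr19	14384925	16034584	1649659	De novo	pathogenic	19p13.12 deletion	simple
P39	del	22q11.21	chr22	18890162	20311554	1421392	De novo	pathogenic	22q11.2 deletion	simple
P40	del	22q11.21	chr22	18661758	21684798	3023040	De novo	pathogenic	22q11.2 deletion	simple
P41	del	22q11.21	chr22	18661758	21684798	3023040	De novo	pathogenic	22q11.2 deletion	simple
P42	del	22q11.21	chr22	18818429	21661436	2843007	Pat	pathogenic	22q11.2 deletion	simple
P43	dup	22q11.21	chr22	18890162	21464056	2573894	Pat	pathogenic	22q11.2 duplication	simple
P44	del	22q11.21q11.23	chr22	21759572	23822925	2063353	Unk	pathogenic	22q11.2 deletion, distal	simple
P45	del	22q11.21q11.22	chr22	21468437	22959609	1491172	Not mat	pathogenic	22q11.2 deletion, distal	simple
P45	dup	3p26.3	chr3	857110	1414719	557609	Not mat	uncertain	Uncertain	simple
P46	del	22q11.22q11.23	chr22	23012069	23648827	636758	Mat	pathogenic	22q11.2 deletion, distal	simple
P47	del	22q11.22q11.23	chr22	23063178	23696464	633286	Unk	pathogenic	22q11.2 deletion, distal	simple
P48	del	3p26.3	chr3	73603	1273300	1199697	De novo	pathogenic	Unbalanced translocation	unbalanced_translocation
P48	dup	11q22.3q25	chr11	106251478	134668665	28417187	--	pathogenic	Unbalanced translocation	unbalanced_translocation
P49	del	3p24.1	chr3	28719852	30169971	1450119	Unk	pathogenic	Complex rearrangement	complex_component
P49	dup	3q11.2q13.31	chr3	93558505	115890384	22331879	--	pathogenic	Complex rearrangement	complex_component
P50	del	3q25.33	chr3	159252702	160555217	1302515	De novo	uncertain	Uncertain	simple
P50	del	13q31.2q32.1	chr13	89522636	95065310	5542674	De novo	pathogenic	Feingold syndrome	simple
P51	del	7q22.1q22.3	chr7	102358320	105487655	3129335	De novo	pathogenic	Clinically relevant	simple
P52	del	10p15.3p14	chr10	269695	11579546	11309851	De novo	pathogenic	Unbalanced translocation	unbalanced_translocation
P52	dup	6q27	chr6	169505179	170694486	1189307	--	uncertain	Uncertain	simple
P53	dup	10p15.3p12.31	chr10	119794	19509585	19389791	Not mat	pathogenic	Complex rearrangement	complex_component
P53	dup	13q11q12.3	chr13	19440913	31031907	11590994	Not mat	pathogenic	Complex rearrangement	complex_component
P54	dup	10q26.11q26.3	chr10	120306959	135434409	15127450	De novo	pathogenic	10qter duplication	simple
P55	del	12q15q21.1	chr12	70555659	73153191	2597532	De novo	pathogenic	Clinically relevant	simple
P56	dup	12q21.32q23.1	chr12	88684581	101464859	12780278	De novo	pathogenic	Insertional translocation	insertional_translocation
P57	del	13q33.2q34	chr13	106648660	115105655	8456995	Not mat	pathogenic	13qter deletion	simple
P58	dup	14q11.2	chr14	21244696	22250879	1006183	De novo	pathogenic	14q11.2 microduplication	simple
P59	del	14q12	chr14	29781404	30552936	771532	De novo	pathogenic	14q12 deletion, non-critical	simple
P59	dup	4p16.1	chr4	10068064	10529023	460959	Mat	likely_benign	Likely benign	simple
P60	del	Xp22.12p22.13	chrX	18214020	19833634	1619614	Unk	pathogenic	Rett syndrome-like	simple
P61	dup	Xp22.33	chrX	75943	2685605	2609662	De novo	pathogenic	Complex rearrangement	complex_component
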