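locus	rsid	chrom	snv_pos	nea	ea	eaf	cpg_index	cg_id	cpg_pos	discovery_p	genes	annotation
1	rs11583641	1	183906245	T	C	0.83	1		183911970		COLGALT2	Intronic; enhancer
1	rs11583641	1	183906245	T	C	0.83	2		183911999		COLGALT2	Intronic; enhancer
1	rs11583641	1	183906245	T	C	0.83	3		183912014		COLGALT2	Intronic; enhancer
1	rs11583641	1	183906245	T	C	0.83	4		183912020		COLGALT2	Intronic; enhancer
1	rs11583641	1	183906245	T	C	0.83	5		183912154		COLGALT2	Intronic; enhancer
1	rs11583641	1	183906245	T	C	0.83	6		183912187		COLGALT2	Intronic; enhancer
1	rs11583641	1	183906245	T	C	0.83	7	cg18131582	183912305	0.003	COLGALT2	Intronic; enhancer
1	rs11583641	1	183906245	T	C	0.83	8		183912397		COLGALT2	Intronic; enhancer
2	rs6976	3	52728804	C	T	0.41	1	cg18099408	52552593	3.73e-6	GNL3;SPCS1	Exonic
2	rs6976	3	52728804	C	T	0.41	2		52552598		GNL3;SPCS1	Exonic
2	rs6976	3	52728804	C	T	0.41	3		52552602		GNL3;SPCS1	Exonic
3	rs10948172	6	44777691	A	G	0.20	1	cg13979708	44695318	6.2e-5	SUPT3H;RUNX2	Intergenic
3	rs10948172	6	44777691	A	G	0.20	2	cg19254793	44695348	9.00e-3	SUPT3H;RUNX2	Intergenic
3	rs10948172	6	44777691	A	G	0.20	3	cg20913747	44695427	4.9e-12	SUPT3H;RUNX2	Intergenic
3	rs10948172	6	44777691	A	G	0.20	4	cg18551225	44695536	1.12e-10	SUPT3H;RUNX2	Intergenic
3	rs10948172	6	44777691	A	G	0.20	5		44695543		SUPT3H;RUNX2	Intergenic
3	rs10948172	6	44777691	A	G	0.20	6		44695547		SUPT3H;RUNX2	Intergenic
4	rs11780978	8	145034852	G	A	0.23	1		145001361		PLEC	Gene body; transcribed
4	rs11780978	8	145034852	G	A	0.23	2		145001378		PLEC	Gene body; transcribed
4	rs11780978	8	145034852	G	A	0.23	3		145001384		PLEC	Gene body; transcribed
4	rs11780978	8	145034852	G	A	0.23	4		145001406		PLEC	Gene body; transcribed
4	rs11780978	8	145034852	G	A	0.23	5	cg19405177	145001428	3.33e-17	PLEC	Gene body; transcribed
4	rs11780978	8	145034852	G	A	0.23	6		145001444		PLEC	Gene body; transcribed
4	rs11780978	8	145034852	G	A	0.23	7		145001464		PLEC	Gene body; transcribed
4	rs11780978	8	145034852	G	A	0.23	8		145001485		PLEC	Gene body; transcribed
4	rs11780978	8	145034852	G	A	0.23	9	cg14598846	145008909	2.72e-19	PLEC	Gene body; transcribed
4	rs11780978	8	145034852	G	A	0.23	10		145008918		PLEC	Gene body; transcribed
4	rs11780978	8	145034852	G	A	0.23	11		145008927		PLEC	Gene body; transcribed
4	rs11780978	8	145034852	G	A	0.23	12		145008930		PLEC	Gene body; transcribed
5	rs3204689	15	58246802	C	G	0.26	1	cg12031962	58353849	2.0e-8	ALDH1A2	Intronic; repressed
5	rs3204689	15	58246802	C	G	0.26	2		58353861		ALDH1A2	Intronic; repressed
6	rs143384;rs143383	20	34025756;34025983	T;C	C;T	0.47;0.45	1	cg14752227	34000481	0.010	GDF5	Intronic
6	rs143384;rs143383	20	34025756;34025983	T;C	C;T	0.47;0.45	2		34000519		GDF5	Intronic
7	rs6516886	21	30393664	T	A	0.41	1	cg00065302	30366250	0.040	RWDD2B	Intergenic
7	rs6516886	21	30393664	T	A	0.41	2	cg05468028	30391383	0.006	RWDD2B	Intronic; promoter
7	rs6516886	21	30393664	T	A	0.41	3		30391385		RWDD2B	Intronic; promoter
7	rs6516886	21	30393664	T	A	0.41	4	cg18001427	30391784	0.010	RWDD2B	Intergenic; promoter
7	rs6516886	21	30393664	T	A	0.41	5	cg20220242	30392188	2.40e-6	RWDD2B	Intergenic; promoter
7	rs6516886	21	30393664	T	A	0.41	6	cg16140273	30455616	0.010	RWDD2B	Intronic; transcribed
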