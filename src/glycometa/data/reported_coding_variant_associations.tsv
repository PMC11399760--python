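trait	rsid	gene	protein_consequence	effect_allele	other_allele	eaf	beta	se	p	n	previous_association	previous_locus
FG	rs1886686	WDR78	p.G12A	G	C	0.739	0.014	0.002	2.24e-11	123558	Novel
HbA1c	rs267738	CERS2	p.E106A	G	T	0.186	-0.01	0.002	6.96e-10	144043	HbA1c	CERS2
HbA1c	rs863362	OR10X1	p.W66X	T	C	0.465	0.011	0.001	6.76e-15	114945	HbA1c	SPTA1
HbA1c	rs857725	SPTA1	p.K1693Q	G	T	0.262	0.022	0.001	1.56e-50	143956	HbA1c	SPTA1
HbA1c	rs11887523	MFSD2B	p.A60T	A	G	0.007	-0.072	0.01	1.44e-12	122060	HbA1c	ATAD2B
FG	rs1260326	GCKR	p.L446P	C	T	0.631	0.029	0.002	6.36e-48	129588	FG, FI, 2hGlu	GCKR
FI	rs1260326	GCKR	p.L446P	C	T	0.626	0.024	0.002	5.55e-32	104076	FG, FI, 2hGlu	GCKR
2hGlu	rs1260326	GCKR	p.L446P	C	T	0.618	-0.069	0.009	4.48e-15	57813	FG, FI, 2hGlu	GCKR
FG	rs35720761	THADA	p.C845Y	T	C	0.108	-0.018	0.003	4.35e-9	129622	T2D, FG	THADA
HbA1c	rs35720761	THADA	p.C845Y	C	T	0.113	0.014	0.002	2.58e-12	144001	T2D, FG	THADA
FG	rs7578597	THADA	p.T897A	C	T	0.106	-0.019	0.003	1.99e-8	113162	T2D, FG	THADA
FI	rs7607980	COBLL1	p.N901D	C	T	0.128	-0.032	0.003	1.30e-24	97817	FI	COBLL1
FG	rs2232323	G6PC2	p.Y207S	C	A	0.006	-0.129	0.012	1.05e-28	123981	FG, HbA1c	G6PC2
HbA1c	rs2232323	G6PC2	p.Y207S	C	A	0.007	-0.053	0.007	3.25e-13	144038	FG, HbA1c	G6PC2
FG	rs146779637	G6PC2	p.R283X	T	C	0.002	-0.138	0.02	1.78e-12	127278	FG, HbA1c	G6PC2
HbA1c	rs146779637	G6PC2	p.R283X	T	C	0.002	-0.074	0.012	4.58e-10	141728	FG, HbA1c	G6PC2
FI	rs1983210	OBSL1	p.E1365D	G	C	0.729	0.016	0.003	8.48e-10	79767	Novel
FI	rs3183099	OBSL1	splice region variant	A	G	0.226	-0.013	0.002	4.70e-8	100713	Novel
FI	rs1801282	PPARG	p.P12A	G	C	0.117	-0.031	0.003	3.50e-23	98631	FI	PPARG
HbA1c	rs35726701	RNF123	p.K596E	G	A	0.019	0.025	0.005	4.19e-8	131203	HbA1c	USP4
FG	rs5400	SLC2A2	p.T110I	A	G	0.161	-0.022	0.003	2.14e-17	129591	FG, HbA1c	SLC2A2
HbA1c	rs5400	SLC2A2	p.T110I	A	G	0.153	-0.013	0.002	2.27e-13	144012	FG, HbA1c	SLC2A2
HbA1c	rs223705	EGF	p.M708I	A	G	0.374	-0.007	0.001	2.11e-7	121204	HbA1c	EGF
HbA1c	rs7683365	GYPB	p.T48M	A	G	0.312	0.012	0.002	1.61e-8	45191	HbA1c	FREM3
FG	rs146886108	ANKH	p.R187Q	T	C	0.004	-0.088	0.014	5.67e-10	129647	T2D	ANKH
HbA1c	rs31244	SV2C	p.D543N	A	G	0.083	0.012	0.002	6.05e-8	144000	Novel
FG	rs6235	PCSK1	p.S690T	G	C	0.264	-0.022	0.002	9.22e-24	123560	FG	PCSK1
2hGlu	rs2549782	ERAP2	p.K392N	T	G	0.519	-0.055	0.009	6.81e-10	57836	2hGlu	ERAP2
HbA1c	rs35742417	RREB1	p.S1499Y	A	C	0.173	-0.01	0.002	3.76e-9	143967	FG, T2D	RREB1
FG	rs35742417	RREB1	p.S1499Y	A	C	0.183	-0.019	0.002	1.27e-16	129577	FG, T2D	RREB1
HbA1c	rs1799945	HFE	p.H63D	G	C	0.129	-0.023	0.002	1.20e-30	128354	HbA1c	HFE, HIST1H4A
HbA1c	rs1800562	HFE	p.C279Y	A	G	0.051	-0.042	0.003	3.30e-47	138093	HbA1c	HFE, HIST1H4A
FG	rs10305492	GLP1R	p.A316T	A	G	0.014	-0.08	0.008	2.37e-25	129601	FG	GLP1R
HbA1c	rs35332062	MLXIPL	p.A358V	A	G	0.117	0.011	0.002	6.18e-9	144042	HbA1c	MLXIPL
HbA1c	rs3812316	MLXIPL	p.Q241H	G	C	0.112	0.012	0.002	2.15e-8	108605	HbA1c	MLXIPL
FG	rs194524	STEAP2	p.R456Q	A	G	0.523	0.01	0.002	7.65e-8	129629	FG, T2D, RG	STEAP2-AS1
HbA1c	rs34664882	ANK1	p.A1503V	A	G	0.026	-0.049	0.004	2.43e-39	144034	HbA1c	ANK1
FG	rs13266634	SLC30A8	p.R276W	T	C	0.305	-0.029	0.002	1.63e-46	129614	FG, HbA1c, T2D	SLC30A8
HbA1c	rs13266634	SLC30A8	p.R276W	T	C	0.300	-0.015	0.001	8.50e-28	143982	FG, HbA1c, T2D	SLC30A8
HbA1c	rs11557154	DCAF12	p.R113Q	T	C	0.138	-0.009	0.002	1.70e-7	144045	T2D, HbA1c	Mahajan 2022 from CMD KP
FG	rs17853166	IKBKAP	p.S251G	C	T	0.026	-0.037	0.006	4.82e-11	129640	FG	IKBKAP
HbA1c	rs60980157	GPSM1	p.S391L	T	C	0.246	-0.013	0.002	6.71e-17	118824	FG, T2D	GPSM1
FG	rs60980157	GPSM1	p.S391L	T	C	0.254	-0.014	0.002	2.35e-9	110915	FG, T2D	GPSM1
HbA1c	rs906220	HK1	p.H7R	G	A	0.916	0.025	0.003	2.16e-21	94970	HbA1c	HK1
FG	rs701865	PDE6C	p.S270T	A	T	0.366	-0.01	0.002	1.14e-7	118580	FG, RG	PDE6C
HbA1c	rs61732434	OR51V1	p.S161N	T	C	0.008	-0.052	0.009	1.75e-8	127507	HbA1c	HBB
HbA1c	rs415895	SWAP70	p.Q447E	G	C	0.641	-0.013	0.001	1.15e-21	138028	HbA1c	SWAP70
HbA1c	rs117706710	AMPD3	p.V311L	T	G	0.009	0.037	0.006	2.32e-10	144048	HbA1c	AMPD3
FG	rs2167079	ACP2	p.R29Q	T	C	0.340	0.016	0.002	7.99e-15	129580	FG	MADD
HbA1c	rs35233100	MADD	p.R766X	T	C	0.055	-0.015	0.003	1.13e-8	144034	FG	MADD
FG	rs35233100	MADD	p.R766X	T	C	0.054	-0.029	0.004	1.46e-12	126231	FG	MADD
FG	rs56200889	ARAP1	p.Q802E	C	G	0.270	-0.016	0.002	1.79e-14	122674	FG	ARAP1
HbA1c	rs643788	DPAGT1	p.I393V	C	T	0.425	-0.006	0.001	1.77e-7	144009	HbA1c	C2CD2L
FI	rs145878042	RAPGEF3	p.L300P	G	A	0.011	-0.054	0.01	1.15e-7	91485	FI/HbA1c	HDAC7/PFKM
HbA1c	rs2732481	ZNF641	p.Q363P	G	T	0.315	-0.009	0.001	2.07e-11	142280	HbA1c	SENP1
HbA1c	rs3184504	SH2B3	p.W262R	C	T	0.567	0.007	0.001	5.98e-8	138551	HbA1c	ATXN2
2hGlu	rs1169288	HNF1A	p.I75L	C	A	0.345	0.06	0.011	7.90e-9	44278	T2D, 2hGlu	HNF1A
HbA1c	COSM147717	ATP11A	p.M317V	G	A	0.748	0.009	0.001	3.77e-12	144022	HbA1c	ATP11A,TUBGCP3
HbA1c	rs229587	SPTB	p.S439N	T	C	0.357	0.007	0.001	2.60e-8	134780	HbA1c	SPTB
HbA1c	rs35097172	SLC25A47	splice region variant, 5' UTR variant	T	C	0.216	-0.008	0.002	5.67e-8	144028	FG	SLC25A47
2hGlu	rs3784634	VPS13C	p.R974K	T	C	0.540	-0.069	0.011	6.40e-10	37217	2hGlu	VPS13C/C2CD4A/C2CD4B
HbA1c	rs3747481	PRR14	p.P359L	T	C	0.261	0.009	0.002	3.30e-8	103338	HbA1c	ITGAD
HbA1c	rs201226914	PIEZO1	p.L939M	T	G	0.002	-0.159	0.015	4.42e-26	144024	HbA1c	CDT1,CYBA
2hGlu	rs72839768	DVL2	p.T529I	A	G	0.020	0.197	0.03	4.10e-11	57866	T2D, 2hGlu	SLC16A13
HbA1c	rs2748427	TMC6	p.W125R	G	A	0.233	0.027	0.002	8.56e-70	132326	HbA1c	TMC6
HbA1c	rs7225887	B3GNTL1	p.A163T	T	C	0.211	-0.015	0.002	5.73e-22	125749	HbA1c	FN3KRP, FN3K
HbA1c	rs35413309	RGS9BP	p.A223V	T	C	0.030	-0.02	0.004	1.42e-8	141598	HbA1c	PDCD5
2hGlu	rs1800437	GIPR	p.E318Q	C	G	0.217	0.103	0.011	2.59e-23	56252	2hGlu	GIPR
FG	rs17265513	ZHX3	p.N310S	C	T	0.188	0.016	0.002	2.59e-10	126253	FG	ZHX3
HbA1c	rs855791	TMPRSS6	p.V727A	G	A	0.577	-0.019	0.001	9.46e-51	143907	HbA1c	TMPRSS6
FG	rs15943	MAP3K15	p.Q1083E	C	G	0.005	-0.084	0.014	2.83e-9	67004	glucose	PDHA1/MAP3K15
FG	rs56381411	MAP3K15	p.G670S	T	C	0.005	-0.085	0.013	1.51e-11	62319	glucose	PDHA1/MAP3K15
HbA1c	rs2229241	RENBP	splice acceptor variant	C	T	0.012	-0.123	0.007	1.14e-62	95622	HbA1c	G6PD
HbA1c	rs1050828	G6PD	p.V68M	T	C	0.007	-0.334	0.008	7.41e-322	112209	HbA1c	G6PD
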