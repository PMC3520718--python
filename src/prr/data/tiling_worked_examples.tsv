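gene_id	symbol	root_response	root_recovery	root_class	shoot_response	shoot_recovery	shoot_class	group
AT4G01060	CPL3/ETC3	4.291	-3.748	IPR	1.476	-1.505	IPR	systemic
AT5G43300	GDPD3	4.272	-4.045	IPR	2.121	-1.893	IPR	systemic
AT3G09922	IPS1	5.971	-4.591	IPR	6.572	-5.800	IPR	systemic
AT4G19038	LCR15	1.376	-2.223	LNR	1.143	-1.756	LNR	systemic
AT3G61172	LCR8	0.412	-1.981	LNR	0.518	-1.667	LNR	systemic
AT2G41240	BHLH100	-2.631	1.024	PNR	-3.980	1.716	INR	systemic
AT3G07005	LCR43	-1.692	0.274	PNR	1.687	-0.321	PPR	systemic
AT1G73607	LCR65	-2.178	-0.235	PNR	1.417	-1.490	IPR	systemic
AT3G56970	ORG2	-1.625	0.454	PNR	-4.283	1.894	INR	systemic
AT3G61177	LCR53	1.963	-1.140	PPR	-1.302	0.300	PNR	systemic
AT1G73165	CLE1	-1.977	1.924	INR	-0.107	-0.097	BAR	root_specific
AT2G31081	CLE4	-2.012	2.875	INR	1.168	-0.746	BAR	root_specific
AT2G31082	CLE7	-1.952	2.312	INR	0.111	0.121	BAR	root_specific
AT5G24920	GDU5	-2.877	3.590	INR	0.217	0.223	BAR	root_specific
AT3G06985	LCR44	-1.885	2.264	INR	1.002	-0.650	BAR	root_specific
AT3G49570	LSU3	-2.308	1.684	INR	0.613	0.096	BAR	root_specific
AT4G18197	PUP7	-1.770	1.755	INR	0.544	-0.300	BAR	root_specific
AT1G54760	AGL85	1.941	-2.146	IPR	-0.136	-0.280	BAR	root_specific
AT5G06905	CYP712A2	2.089	-2.979	IPR	-0.110	-0.599	BAR	root_specific
AT3G30725	GDU6	3.627	-5.125	IPR	-0.030	-0.020	BAR	root_specific
AT2G32960	PFA-DSP2	1.810	-1.706	IPR	1.185	-1.223	BAR	root_specific
AT3G09400	PLL3	2.523	-2.929	IPR	0.978	-0.054	BAR	root_specific
AT4G27920	RCAR4	2.259	-2.132	IPR	0.734	-0.431	BAR	root_specific
AT1G53130	GRI	-0.375	-1.756	LNR	-0.056	-0.117	BAR	root_specific
AT3G61182	LCR54	0.226	-1.759	LNR	-0.763	-0.202	BAR	root_specific
AT2G14365	LCR84	0.519	-1.936	LNR	0.756	-0.101	BAR	root_specific
AT4G10115	SCRL20	0.348	-2.985	LNR	-0.297	-0.485	BAR	root_specific
AT4G29305	LCR25	-1.368	2.295	LPR	0.973	-0.521	BAR	root_specific
AT4G06746	RAP2.9	-1.617	3.125	LPR	-0.404	0.512	BAR	root_specific
AT4G23170	EP1	-2.487	0.662	PNR	-0.033	-0.134	BAR	root_specific
AT4G09795	LCR13	-2.395	1.119	PNR	-0.939	0.103	BAR	root_specific
AT3G23167	LCR39	-1.694	0.502	PNR	0.556	-1.297	BAR	root_specific
AT4G18195	PUP8	-1.820	1.335	PNR	-0.136	-0.001	BAR	root_specific
AT3G23715	SCRL13	-2.088	0.971	PNR	1.289	0.501	BAR	root_specific
AT2G20825	ULT2	-1.640	0.337	PNR	0.339	0.139	BAR	root_specific
AT5G45105	ZIP8	-2.392	0.846	PNR	0.284	-1.101	BAR	root_specific
AT4G22210	LCR85	1.664	0.028	PPR	0.399	-0.238	BAR	root_specific
AT1G60815	RALFL7	1.728	-0.550	PPR	0.315	0.319	BAR	root_specific
AT1G47510	AT5PTASE11	0.182	-0.184	BAR	-1.362	1.610	INR	shoot_specific
AT1G66145	CLE18	-0.570	-0.135	BAR	-1.422	1.680	INR	shoot_specific
AT4G11485	LCR11	-0.969	-1.131	BAR	-1.695	1.849	INR	shoot_specific
AT4G13890	SHM5	-0.177	-0.165	BAR	-1.534	1.421	INR	shoot_specific
AT4G10767	SCRL21	-0.211	-0.470	BAR	1.459	-2.258	IPR	shoot_specific
AT2G30432	TCL1	0.062	-0.924	BAR	1.680	-1.893	IPR	shoot_specific
AT1G06280	LBD2	-0.667	-0.194	BAR	0.729	-1.385	LNR	shoot_specific
AT4G29280	LCR22	-0.461	-0.171	BAR	0.485	-1.779	LNR	shoot_specific
AT3G04430	NAC049	1.550	-0.809	BAR	0.731	-1.440	LNR	shoot_specific
AT1G23147	RALFL3	-0.093	-0.201	BAR	1.262	-2.229	LNR	shoot_specific
AT5G45875	SCRL27	0.864	0.235	BAR	0.754	-1.712	LNR	shoot_specific
AT4G31380	FLP1	0.549	-0.073	BAR	-0.234	1.555	LPR	shoot_specific
AT4G29283	LCR21	-1.583	-0.275	BAR	0.150	1.783	LPR	shoot_specific
AT2G14935	LCR40	0.461	0.290	BAR	-0.469	1.423	LPR	shoot_specific
AT2G12465	LCR50	0.500	-1.178	BAR	-0.942	1.510	LPR	shoot_specific
AT2G02147	LCR73	0.599	1.466	BAR	-0.563	1.383	LPR	shoot_specific
AT2G04425	LCR82	1.334	0.118	BAR	-1.264	1.380	LPR	shoot_specific
AT4G36950	MAPKKK21	0.228	-0.210	BAR	-0.776	1.478	LPR	shoot_specific
AT5G44430	PDF1.2 C	0.682	-1.123	BAR	-0.528	1.747	LPR	shoot_specific
AT2G05117	SCRL9	-0.182	0.668	BAR	-1.005	1.595	LPR	shoot_specific
AT5G37415	AGL105	0.684	-0.214	BAR	-1.931	0.608	PNR	shoot_specific
AT2G45110	EXPB4	-0.018	0.286	BAR	-1.495	0.106	PNR	shoot_specific
AT1G07900	LBD1	-0.174	-0.103	BAR	-1.834	0.837	PNR	shoot_specific
AT3G43083	LCR33	-0.830	0.966	BAR	-1.956	0.748	PNR	shoot_specific
AT4G39917	LCR45	-0.321	0.020	BAR	-1.897	0.452	PNR	shoot_specific
AT5G14490	NAC085	0.099	-0.557	BAR	-1.365	0.724	PNR	shoot_specific
AT4G11653	RALFL29	-0.280	-0.607	BAR	-1.900	0.762	PNR	shoot_specific
AT1G60625	RALFL6	-0.668	0.726	BAR	-1.671	0.373	PNR	shoot_specific
AT4G24230	ACBP3	1.295	-0.391	BAR	1.546	-1.194	PPR	shoot_specific
AT4G29273	LCR23	0.128	-0.851	BAR	1.352	-0.802	PPR	shoot_specific
AT2G19020	RALFL10	-1.217	0.276	BAR	1.745	-1.112	PPR	shoot_specific
AT2G34825	RALFL20	0.240	0.456	BAR	1.375	-0.603	PPR	shoot_specific
AT5G08150	SOB5	1.213	-1.337	BAR	1.944	-1.205	PPR	shoot_specific
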