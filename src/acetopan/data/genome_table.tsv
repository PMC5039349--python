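strain	isolation	temperature_c	genome_size_bp	gc_percent	n_genes	n_cds	accession	in_analysis_panel
Acetobacterium woodii DSM 1030	Mud	30	4044777	39.3	3649	3521	CP002987	1
Acetohalobium arabaticum DSM 5501	Lagoons	37	2469596	36.6	2396	2286	CP002105	1
Carboxydothermus hydrogenoformans Z-2901	Hotspring	78	2401520	42	2495	2406	CP000141	1
Clostridium aceticum DSM 1496	Mud	30	4201318	35.3	3847	3705	CP009687	1
Clostridium autoethanogenum DSM 10061	Rabbit faeces	37	4352205	31.1	3983	3741	CP006763	1
Clostridium autoethanogenum DSM 10061	Rabbit faeces	37	4352446	31.1	4069	3964	CP012395	0
Clostridium carboxidivorans P7	Lagoons	37	5732880	29.9	5167	5004	CP011803	1
Clostridium ljungdahlii DSM 13528	Chicken yard waste	37	4630065	31.1	4234	4081	CP001666	1
Clostridium scatologenes ATCC 25775	Soil	37	5749410	29.6	5183	4974	CP009933	1
Clostridium sticklandii DSM 519	Mud	37	2715461	33.3	2625	2476	FP565809	0
Eubacterium limosum KIST 612	Anaerobic digester fluid	37	4316707	47.5	4089	3966	CP002273	1
Eubacterium limosum SA11	Sheep lumen	37	4150332	47.4	3902	3805	CP011914	0
Moorella thermoacetica ATCC 39073	Horse faeces	55	2628784	55.8	2613	2463	CP000232	1
Moorella thermoacetica DSM 521	Horse faeces	55	2527564	55.9	2518	2405	CP012369	0
Moorella thermoacetica DSM 2955	Horse faeces	55	2623349	55.8	2609	2508	CP012370	0
Clostridium difficile 630	Human intestine	37	4290252	29.1	3971	3756	AM180355	1
Clostridium difficile CD196	Human intestine	37	4110554	28.7	3526	3487	FN538970	0
Clostridium difficile M120	Human intestine	37	4047729	28.7	3707	3502	FN665653	0
Clostridium difficile 630	Human intestine	37	4274806	29	3972	3794	CP010905	0
Clostridium difficile 630 Deltaerm	Human intestine	37	4293049	29.1	3990	3816	LN614756	0
Thermacetogenium phaeum DSM 12270	Sludge	60	2939057	53.9	2894	2766	CP003732	1
Thermoanaerobacter kivui LKT-1	Lake sediment	65	2397824	35	2425	2198	CP009170	1
Treponema primitia ZAS-2	Termite	30	4059867	50.8	3536	3427	CP001843	1
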