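# Published per-library summary statistics for 19 public animal small-RNA
# sequencing runs in which plant miRNA reads reached at least 0.050% of
# animal miRNA reads. Count columns are inputs; percent and share columns
# are the published derived values used as a regression fixture.
library_id	organism	source	total_mirna_reads	plant_reads	pct_plant_of_animal	top_plant_family	top_family_reads	top_family_pct_of_plant	top_family_pct_of_animal	top_family_rank_in_animal
SRR039190	human	blood	1175650	5342	0.456	miR168	2856	53.5	0.244	42
SRR036085	pea aphid	whole insect	692109	1841	0.267	miR168	1695	92.1	0.246	18
SRR080701	pig	abdominal fat	2572468	6709	0.261	miR535	2835	42.3	0.110	36
SRR042444	mouse	bone marrow	3620895	8412	0.233	miR168	8411	100.0	0.233	15
SRR042463	mouse	spleen	2092533	4500	0.216	miR168	4499	100.0	0.215	24
SRR042454	mouse	lymph nodes	2019824	4274	0.212	miR168	4274	100.0	0.212	14
SRR042443	mouse	bone marrow	3759698	7738	0.206	miR168	7732	99.9	0.206	18
SRR039191	human	blood	2195526	4153	0.190	miR168	3627	87.3	0.166	28
SRR042448	mouse	spleen	2845389	4549	0.160	miR168	4548	100.0	0.160	16
SRR042481	mouse	pancreas	2358808	3693	0.157	miR168	3693	100.0	0.157	23
SRR042445	mouse	spleen	3165427	4952	0.157	miR168	4951	100.0	0.157	15
SRR042451	mouse	spleen	2238211	3397	0.152	miR168	3397	100.0	0.152	22
SRR042467	mouse	spleen	3308658	4264	0.129	miR168	4262	100.0	0.129	23
SRR042456	mouse	bone marrow	2645549	3344	0.127	miR168	3344	100.0	0.127	32
SRR042446	mouse	spleen	2367601	2016	0.085	miR168	2015	100.0	0.085	24
SRR035544	silkworm	whole body	1111992	705	0.063	miR168	508	72.1	0.046	28
SRR042462	mouse	bone marrow	2133939	1279	0.060	miR168	1276	99.8	0.060	37
SRR042475	mouse	embryonic fibroblasts	2438884	1420	0.058	miR168	1420	100.0	0.058	51
SRR042457	mouse	bone marrow	3370053	1777	0.053	miR168	1777	100.0	0.053	31
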