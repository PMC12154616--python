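# Published genome-wide dark-region summary statistics, primary-only alignments.
# Ten ~30x human WGS samples per platform, aligned to four references;
# columns mirror the per-class summary: bases, regions, mean/median region length.
platform	reference	dark_class	n_bases	n_regions	mean_len	median_len
Illumina100	HG19	dark_by_depth	1167989	11988	97.43	57
Illumina100	HG19	dark_by_mapq	32837051	51403	638.82	137
Illumina100	HG19	all_dark	34005040	58330	582.98	115
Illumina250	HG19	dark_by_depth	1832263	11219	163.32	102
Illumina250	HG19	dark_by_mapq	26229311	19364	1354.54	583
Illumina250	HG19	all_dark	28061574	25971	1080.50	338
PacBio	HG19	dark_by_depth	1319120	324	4071.36	1801
PacBio	HG19	dark_by_mapq	7460817	290	25726.96	10843.50
PacBio	HG19	all_dark	8779937	502	17489.91	3337
ONT	HG19	dark_by_depth	1464751	195	7511.54	2176
ONT	HG19	dark_by_mapq	691318	24	28804.90	1805.50
ONT	HG19	all_dark	2156069	211	10218.34	2176
Illumina100	HG38_noalt	dark_by_depth	3721688	40806	91.20	55
Illumina100	HG38_noalt	dark_by_mapq	73843911	105606	699.24	196
Illumina100	HG38_noalt	all_dark	77565599	96787	801.41	158
Illumina250	HG38_noalt	dark_by_depth	9163182	37231	246.12	133
Illumina250	HG38_noalt	dark_by_mapq	47018216	53262	882.77	437
Illumina250	HG38_noalt	all_dark	56181398	63748	881.30	347
PacBio	HG38_noalt	dark_by_depth	16636630	1141	14580.74	3749
PacBio	HG38_noalt	dark_by_mapq	35215658	1257	28015.64	8924
PacBio	HG38_noalt	all_dark	51852288	1281	40477.98	5005
ONT	HG38_noalt	dark_by_depth	14664911	685	21408.63	3114
ONT	HG38_noalt	dark_by_mapq	30564861	569	53716.80	1286
ONT	HG38_noalt	all_dark	45229772	883	51222.84	2887
Illumina100	HG38_alt	dark_by_depth	6914302	54812	126.15	61
Illumina100	HG38_alt	dark_by_mapq	117906741	128622	916.69	186
Illumina100	HG38_alt	all_dark	124821043	120689	1034.24	163
Illumina250	HG38_alt	dark_by_depth	12134914	45093	246.12	138
Illumina250	HG38_alt	dark_by_mapq	90036424	64821	1389.01	472
Illumina250	HG38_alt	all_dark	102171338	74705	1367.66	383
PacBio	HG38_alt	dark_by_depth	21763221	1326	16412.69	4910.50
PacBio	HG38_alt	dark_by_mapq	60183222	1781	33791.81	10859
PacBio	HG38_alt	all_dark	81946443	1859	44080.93	6965
ONT	HG38_alt	dark_by_depth	14708016	687	21409.05	3083
ONT	HG38_alt	dark_by_mapq	34475006	620	55604.85	1143.50
ONT	HG38_alt	all_dark	49183022	928	52998.95	2606.50
Illumina100	CHM13	dark_by_depth	11269696	97770	115.27	68
Illumina100	CHM13	dark_by_mapq	206689498	236580	873.66	198
Illumina100	CHM13	all_dark	217959194	208620	1044.77	169
Illumina250	CHM13	dark_by_depth	11781153	55512	212.23	132
Illumina250	CHM13	dark_by_mapq	171496781	107573	1594.24	754
Illumina250	CHM13	all_dark	183277934	102599	1786.35	600
PacBio	CHM13	dark_by_depth	25762200	2091	12320.52	4707
PacBio	CHM13	dark_by_mapq	78273227	4094	19119.01	5495
PacBio	CHM13	all_dark	104035427	3397	30625.98	3435
ONT	CHM13	dark_by_depth	26747722	1114	24010.52	1824.50
ONT	CHM13	dark_by_mapq	62833689	1869	33618.88	1266
ONT	CHM13	all_dark	89581411	1551	57757.20	1396
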