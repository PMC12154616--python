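# Published genome-wide dark-region summary statistics with supplementary
# alignments included (only secondary alignments excluded); same grid and
# column layout as the primary-only table.
platform	reference	dark_class	n_bases	n_regions	mean_len	median_len
Illumina100	HG19	dark_by_depth	1134328	12112	93.65	55
Illumina100	HG19	dark_by_mapq	33198012	54010	614.66	132
Illumina100	HG19	all_dark	34332340	59799	574.13	113
Illumina250	HG19	dark_by_depth	1650985	10676	154.64	94
Illumina250	HG19	dark_by_mapq	26294894	20092	1308.72	552
Illumina250	HG19	all_dark	27945879	26108	1070.40	330
PacBio	HG19	dark_by_depth	1231183	308	3997.35	1740
PacBio	HG19	dark_by_mapq	7427862	295	25179.19	11463.00
PacBio	HG19	all_dark	8659045	493	17563.99	3671
ONT	HG19	dark_by_depth	866404	136	6370.62	1838
ONT	HG19	dark_by_mapq	595222	32	18600.69	402.50
ONT	HG19	all_dark	1461626	159	9192.62	1885
Illumina100	HG38_noalt	dark_by_depth	3478655	39223	88.69	54
Illumina100	HG38_noalt	dark_by_mapq	74509814	106813	697.57	188
Illumina100	HG38_noalt	all_dark	77988469	97977	795.99	154
Illumina250	HG38_noalt	dark_by_depth	8607828	37494	229.58	127
Illumina250	HG38_noalt	dark_by_mapq	47365894	55542	852.80	415
Illumina250	HG38_noalt	all_dark	55973722	64215	871.66	342
PacBio	HG38_noalt	dark_by_depth	15129952	1047	14450.77	3887
PacBio	HG38_noalt	dark_by_mapq	35252149	1413	24948.44	4208
PacBio	HG38_noalt	all_dark	50382101	1520	33146.12	4041
ONT	HG38_noalt	dark_by_depth	11796589	540	21845.54	2869
ONT	HG38_noalt	dark_by_mapq	28879047	534	49450.42	902
ONT	HG38_noalt	all_dark	40675636	807	50403.51	2066
Illumina100	HG38_alt	dark_by_depth	6672223	53523	124.67	60
Illumina100	HG38_alt	dark_by_mapq	118643093	129961	912.91	181
Illumina100	HG38_alt	all_dark	125315316	121722	1029.52	159
Illumina250	HG38_alt	dark_by_depth	11571770	45526	254.18	134
Illumina250	HG38_alt	dark_by_mapq	90385886	67021	1348.62	451
Illumina250	HG38_alt	all_dark	101957656	74979	1359.82	381
PacBio	HG38_alt	dark_by_depth	20733753	1394	14873.57	3963.50
PacBio	HG38_alt	dark_by_mapq	60338607	1950	30942.88	7199
PacBio	HG38_alt	all_dark	81072360	1981	40924.97	6132
ONT	HG38_alt	dark_by_depth	11992613	519	23107.15	3466
ONT	HG38_alt	dark_by_mapq	32779459	679	48276.08	1050.00
ONT	HG38_alt	all_dark	44772072	916	48877.81	2058
Illumina100	CHM13	dark_by_depth	9281454	86932	106.77	64
Illumina100	CHM13	dark_by_mapq	208601378	233786	892.27	194
Illumina100	CHM13	all_dark	217882832	210261	1036.25	163
Illumina250	CHM13	dark_by_depth	11155052	54174	205.91	127
Illumina250	CHM13	dark_by_mapq	171955027	107897	1593.70	743
Illumina250	CHM13	all_dark	183110079	102930	1778.98	600
PacBio	CHM13	dark_by_depth	23154314	2027	11422.95	3577
PacBio	CHM13	dark_by_mapq	73945914	5216	14176.75	1458
PacBio	CHM13	all_dark	97100228	4857	19991.81	1262
ONT	CHM13	dark_by_depth	11214301	610	18384.10	1485.50
ONT	CHM13	dark_by_mapq	61930618	2032	30477.67	919
ONT	CHM13	all_dark	73144919	2000	36572.46	946
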