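row	union_count	count_a	count_b	match_count	category_match_count	rate_a	rate_b	overall_category_rate	overall_rate
stopgain_SNV	15835	14183	14960	13308	-	93.83	88.96	-	84.04
frameshift_insertion	6980	5298	6495	4813	-	90.85	74.10	-	68.95
frameshift_deletion	7491	4547	7380	4436	-	97.56	60.11	-	59.22
stoploss_SNV	946	503	906	463	-	92.05	51.10	-	48.94
splicing	47878	14154	45839	12115	-	85.59	26.43	-	25.30
frameshift_substitution	1960	195	1947	182	-	93.33	9.35	-	9.29
nonsynonymous_SNV	321669	291898	315592	285821	-	97.92	90.57	-	88.86
nonframeshift_insertion	3506	2888	2844	2226	-	77.08	78.27	-	63.49
nonframeshift_deletion	5136	3321	4963	3148	-	94.79	63.43	-	61.29
nonframeshift_substitution	933	226	843	136	-	60.18	16.13	-	14.58
synonymous_SNV	178559	167561	172463	161465	-	96.36	93.62	-	90.43
UTR3	724802	574255	622441	471894	-	82.17	75.81	-	65.11
UTR5	177832	94545	162684	79397	-	83.98	48.80	-	44.65
UTR5_UTR3	2183	292	2092	201	-	68.84	9.61	-	9.21
ncRNA_intronic	8992009	2113428	8244441	1365860	-	64.63	16.57	-	15.19
ncRNA_exonic	654098	140303	597947	84152	-	59.98	14.07	-	12.87
ncRNA_UTR3	53379	10712	47133	4466	-	41.69	9.48	-	8.37
ncRNA_UTR5	10683	1989	9444	750	-	37.71	7.94	-	7.02
ncRNA_splicing	13931	1051	13562	682	-	64.89	5.03	-	4.90
ncRNA_UTR5_ncRNA_UTR3	107	1	106	0	-	0.00	0.00	-	0.00
intronic	29289037	26805864	27743749	25260576	-	94.24	91.05	-	86.25
intergenic	50305202	49797113	41307708	40799619	-	81.93	98.77	-	81.10
downstream	991811	474684	840376	323249	-	68.10	38.46	-	32.59
upstream	910818	440728	762664	292574	-	66.38	38.36	-	32.12
upstream_downstream	53608	15621	47293	9306	-	59.57	19.68	-	17.36
unknown	11205	6215	5703	713	-	11.47	12.50	-	6.36
ALL_LOF	81090	38880	77527	35317	-	90.84	45.55	-	43.55
ALL_LOF_AND_MISSENSE	412334	337213	401769	326648	-	96.87	81.30	-	79.22
ALL_EXONIC	590893	504774	574232	488113	-	96.70	85.00	-	82.61
ALL	80981575	80981575	80981575	69181552	-	85.43	85.43	-	85.43
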