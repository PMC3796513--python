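subject	timepoint	arm	pain_vas	examined_voxels	mean_bq	sd_bq	volume_ml	mean_z	vis	note
1	before	unaffected	5	11675	2086	1371	1.7	2.9	5
1	before	affected	58	11495	2999	1858	110	3.7	406.5
1	after	unaffected	3	11162	1199	668	7	3.5	24.2
1	after	affected	28	11110	1381	767	30	3.3	98.5
2	before	unaffected	5	9825	4664	3748	0.26	2.8	0.7
2	before	affected	65	9626	5952	4699	30.5	3.7	112.6
2	after	unaffected	1	10776	2129	1744	0	0	0	identical mean intensity printed for both arms; probable transcription error
2	after	affected	10	10991	2129	1744	172	4.4	755.4	identical mean intensity printed for both arms; probable transcription error
3	before	unaffected	3	9811	1837	804	0	0	0
3	before	affected	67	10274	3137	2483	186	5.2	970.1
3	after	unaffected	4	10025	1472	773	0	0	0
3	after	affected	35	10299	2258	1953	150	4.7	702.7
4	before	unaffected	0	20009	5316	2404	32	3.3	106.2
4	before	affected	52	17661	5658	2382	31.8	3.3	104.7
5	before	unaffected	4	15012	1432	647	0	0	0
5	before	affected	69	15139	3174	4802	211	12.4	2616.5
5	after	unaffected	8	16057	2184	3024	0	0	0
5	after	affected	29	16753	4740	3922	319	4.6	1462.4
6	before	unaffected	2	16525	1956	663	0	0	0
6	before	affected	41	19007	2537	1696	196	5.4	1064.1
6	after	unaffected	5	18037	1492	754	0	0	0
6	after	affected	25	19571	2734	2280	413	4.8	1973.7
7	before	unaffected	6	12373	2953	1844	0.4	3.7	1.5
7	before	affected	62	15185	6573	6433	318	5.6	1773.6
7	after	unaffected	3	15493	2495	1266	0	0	0
7	after	affected	4	13906	5309	4530	316	5.9	1186.3	printed score inconsistent with printed volume x mean Z (316 x 5.9 = 1864.4); irreconcilable transcription error
8	before	unaffected	7	13718	3056	1118	0.2	2.7	0.5
8	before	affected	68	15010	4501	3109	202	5.3	1072.2
8	after	unaffected	7	13127	2058	766	0	0	0
8	after	affected	67	14828	3783	3486	297	7.1	2120.7
9	before	unaffected	7	13512	1715	916	0	0	0
9	before	affected	49	13118	2023	1466	89	3.5	314.8
9	after	unaffected	3	13204	1966	1133	0	0	0
9	after	affected	2	12409	1485	803	0.3	2.8	0.84
10	before	unaffected	6	15999	2907	1073	0.4	3.3	1.3
10	before	affected	44	16734	3301	1889	123	4	487.8
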