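row_id	kind	N	n	mean_cdna	diff_of_means	ci_half_width	lower	upper	sig	overexpressed_allele	fold_change
8016_4	sample	8	7	2.7290	0.9447	0.2841	0.661	1.229	0.001	AT	1.5295
8036_3	sample	8	8	2.2489	0.4645	0.1243	0.340	0.589	0.0002	AT	1.2603
8036_4	sample	8	8	2.3455	0.5612	0.6067	-0.046	1.168	0.1127	N/A	1.3145
8046_4	sample	8	8	2.0783	0.2940	0.1860	0.108	0.480	0.0174	AT	1.1648
8052_4	sample	8	7	2.2372	0.4528	0.0483	0.405	0.501	1.677E-06	AT	1.2538
8060_5	sample	8	8	2.0232	0.2389	0.0579	0.181	0.297	8.481E-05	AT	1.1339
8062_4	sample	8	8	1.9644	0.1801	0.1141	0.066	0.294	0.017	AT	1.1009
8067_3	sample	8	8	1.5871	-0.1973	0.1887	-0.386	-0.009	0.091	N/A	0.8895
8080_3	sample	8	8	2.5434	0.7590	0.1593	0.600	0.918	3.347E-05	AT	1.4254
8080_5	sample	8	8	2.1789	0.3946	0.0975	0.297	0.492	9.641E-05	AT	1.2212
8081_4	sample	8	8	2.2138	0.4295	0.1887	0.241	0.618	0.003	AT	1.2407
8100_3	sample	8	8	1.9241	0.1398	0.1342	0.006	0.274	0.080	N/A	1.0784
8103_4	sample	8	6	0.6981	-1.0862	0.0220	-1.108	-1.064	2.228E-09	G	0.3912
8110_4	sample	8	8	2.0563	0.2720	0.1438	0.128	0.416	0.0076	AT	1.1525
8111_5	sample	8	7	2.1026	0.3183	0.0708	0.247	0.389	0.0001	AT	1.1784
8122_4	sample	8	8	1.9307	0.1464	0.1292	0.017	0.276	0.0618	N/A	1.0820
8127_3	sample	8	8	2.0927	0.3084	0.1382	0.170	0.447	0.0033	AT	1.1729
8135_3	sample	8	8	1.9250	0.1407	0.2013	-0.061	0.342	0.2131	N/A	1.0788
8135_4	sample	8	7	1.7092	-0.0751	0.1454	-0.220	0.070	0.3502	N/A	0.9579
8136_3	sample	8	8	2.2603	0.4760	0.1183	0.358	0.594	9.988E-05	AT	1.2667
8146_3	sample	8	8	1.8690	0.0847	0.1456	-0.061	0.230	0.2916174	N/A	1.0475
8146_4	sample	8	8	2.1852	0.4009	0.1167	0.284	0.518	0.0003	AT	1.2247
8148_4	sample	8	8	1.9540	0.1697	0.1202	0.050	0.290	0.0278	AT	1.0951
8148_5	sample	8	8	1.9686	0.1843	0.0895	0.095	0.274	0.0049	AT	1.1033
8154_3	sample	8	8	2.0219	0.2376	0.1158	0.122	0.353	0.0050	AT	1.1331
8158_4	sample	8	8	1.8610	0.0767	0.0561	0.021	0.133	0.0315	AT	1.0430
8176_5	sample	8	7	1.8324	0.0481	1.0002	-0.952	1.048	0.9280	N/A	1.0269
8187_3	sample	8	8	1.8010	0.0167	0.0660	-0.049	0.083	0.6349	N/A	1.0094
8187_4	sample	8	8	1.9886	0.2043	0.1132	0.091	0.318	0.0095	AT	1.1145
8189_3	sample	8	8	2.0520	0.2677	0.1564	0.111	0.424	0.0122	AT	1.1500
8199_3	sample	8	8	2.4459	0.6616	0.2383	0.423	0.900	0.0010	AT	1.3708
8199_4	sample	8	8	2.4312	0.6469	0.1697	0.477	0.817	0.0001	AT	1.3625
8199_5	sample	8	8	2.5618	0.7775	0.0762	0.701	0.854	1.95E-07	AT	1.4357
8208_3	sample	8	8	1.8682	0.0839	0.0907	-0.007	0.175	0.113	N/A	1.0470
8208_4	sample	8	8	2.4574	0.6731	0.3703	0.303	1.043	0.009	AT	1.3772
population	stratum	280	273	2.0702	0.2859	0.0538	0.232	0.340	1.258E-21	AT	1.1602
population_edited	stratum	232	232	2.0979	0.3136	0.0446	0.269	0.358	5.656E-32	AT	1.1757
male	stratum	152	149	2.1657	0.3814	0.0756	0.306	0.457	5.07E-18	AT	1.2137
male_edited	stratum	128	128	2.1492	0.3649	0.0650	0.300	0.430	3.409E-20	AT	1.2045
female	stratum	128	124	1.9555	0.1712	0.0711	0.100	0.242	6.353E-06	AT	1.0960
female_edited	stratum	104	104	2.0348	0.2504	0.0571	0.193	0.307	9.278E-14	AT	1.1404
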