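# Bond-angle potentials per residue class (surrogate coil-like wells).
# theta_rad	glycine	proline	generic  (energies in eps)
theta	glycine	proline	generic
0.020000	7.220000	16.934400	15.210000
0.048122	7.007851	16.372197	14.774453
0.076245	6.798866	15.819484	14.345233
0.104367	6.593044	15.276261	13.922340
0.132490	6.390385	14.742529	13.505775
0.160612	6.190890	14.218287	13.095536
0.188735	5.994559	13.703536	12.691624
0.216857	5.801391	13.198275	12.294039
0.244980	5.611386	12.702505	11.902781
0.273102	5.424545	12.216226	11.517850
0.301225	5.240868	11.739436	11.139246
0.329347	5.060354	11.272138	10.766969
0.357469	4.883003	10.814329	10.401019
0.385592	4.708816	10.366011	10.041396
0.413714	4.537793	9.927184	9.688100
0.441837	4.369933	9.497847	9.341131
0.469959	4.205236	9.078001	9.000488
0.498082	4.043703	8.667645	8.666173
0.526204	3.885333	8.266779	8.338185
0.554327	3.730127	7.875404	8.016524
0.582449	3.578085	7.493520	7.701190
0.610572	3.429206	7.121126	7.392182
0.638694	3.283490	6.758222	7.089502
0.666816	3.140938	6.404809	6.793149
0.694939	3.001549	6.060886	6.503123
0.723061	2.865324	5.726454	6.219423
0.751184	2.732262	5.401512	5.942051
0.779306	2.602364	5.086061	5.671006
0.807429	2.475629	4.780100	5.406287
0.835551	2.352058	4.483630	5.147896
0.863674	2.231651	4.196650	4.895832
0.891796	2.114406	3.919161	4.650094
0.919919	2.000326	3.651162	4.410684
0.948041	1.889408	3.392653	4.177600
0.976164	1.781655	3.143636	3.950844
1.004286	1.677064	2.904108	3.730414
1.032408	1.575638	2.674071	3.516312
1.060531	1.477374	2.453524	3.308536
1.088653	1.382275	2.242468	3.107088
1.116776	1.290338	2.040903	2.911966
1.144898	1.201565	1.848828	2.723172
1.173021	1.115956	1.666243	2.540704
1.201143	1.033510	1.493149	2.364563
1.229266	0.954228	1.329545	2.194750
1.257388	0.878109	1.175432	2.031263
1.285511	0.805154	1.030809	1.874103
1.313633	0.735362	0.895677	1.723271
1.341755	0.668734	0.770035	1.578765
1.369878	0.605269	0.653884	1.440586
1.398000	0.544967	0.547223	1.308734
1.426123	0.487829	0.450052	1.183210
1.454245	0.433855	0.362372	1.064012
1.482368	0.383044	0.284183	0.951141
1.510490	0.335397	0.215484	0.844597
1.538613	0.290913	0.156275	0.744380
1.566735	0.249592	0.106557	0.650490
1.594858	0.211435	0.066330	0.562927
1.622980	0.176442	0.035592	0.481691
1.651102	0.144612	0.014346	0.406783
1.679225	0.115945	0.002590	0.338201
1.707347	0.090442	0.000324	0.275946
1.735470	0.068103	0.007549	0.220018
1.763592	0.048927	0.024264	0.170417
1.791715	0.032914	0.050470	0.127143
1.819837	0.020065	0.086166	0.090195
1.847960	0.010380	0.131352	0.059575
1.876082	0.003858	0.186029	0.035282
1.904205	0.000499	0.250197	0.017316
1.932327	0.000304	0.323855	0.005677
1.960449	0.003272	0.407004	0.000365
1.988572	0.009404	0.499643	0.001380
2.016694	0.018700	0.601772	0.008721
2.044817	0.031158	0.713392	0.022390
2.072939	0.046781	0.834502	0.042386
2.101062	0.065567	0.965103	0.068709
2.129184	0.087516	1.105195	0.101358
2.157307	0.112629	1.254776	0.140335
2.185429	0.140905	1.413849	0.185639
2.213552	0.172345	1.582411	0.237270
2.241674	0.206948	1.760465	0.295227
2.269797	0.244715	1.948008	0.359512
2.297919	0.285645	2.145043	0.430123
2.326041	0.329739	2.351567	0.507062
2.354164	0.376997	2.567582	0.590328
2.382286	0.427417	2.793088	0.679920
2.410409	0.481002	3.028084	0.775840
2.438531	0.537749	3.272570	0.878086
2.466654	0.597661	3.526547	0.986660
2.494776	0.660735	3.790015	1.101560
2.522899	0.726973	4.062973	1.222788
2.551021	0.796375	4.345421	1.350342
2.579144	0.868940	4.637360	1.484223
2.607266	0.944669	4.938789	1.624432
2.635388	1.023561	5.249709	1.770967
2.663511	1.105617	5.570119	1.923829
2.691633	1.190836	5.900020	2.083019
2.719756	1.279219	6.239411	2.248535
2.747878	1.370765	6.588293	2.420378
2.776001	1.465474	6.946665	2.598549
2.804123	1.563348	7.314528	2.783046
2.832246	1.664384	7.691881	2.973870
2.860368	1.768584	8.078725	3.171021
2.888491	1.875948	8.475059	3.374500
2.916613	1.986475	8.880883	3.584305
2.944735	2.100166	9.296198	3.800437
2.972858	2.217020	9.721004	4.022896
3.000980	2.337037	10.155300	4.251682
3.029103	2.460218	10.599086	4.486795
3.057225	2.586563	11.052363	4.728235
3.085348	2.716071	11.515130	4.976002
3.113470	2.848742	11.987388	5.230096
3.141593	2.984577	12.469136	5.490517
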