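# Dihedral potentials per residue class (surrogate coil-like, periodic).
phi	glycine	proline	generic
-3.141593	0.000000	0.073450	0.000000
-3.089233	0.002736	0.061580	0.004242
-3.036873	0.010884	0.056055	0.016874
-2.984513	0.024261	0.056733	0.037623
-2.932153	0.042567	0.063347	0.066036
-2.879793	0.065393	0.075520	0.101498
-2.827433	0.092232	0.092774	0.143242
-2.775074	0.122486	0.114539	0.190371
-2.722714	0.155488	0.140170	0.241877
-2.670354	0.190512	0.168961	0.296667
-2.617994	0.226795	0.200167	0.353590
-2.565634	0.263553	0.233017	0.411462
-2.513274	0.300000	0.266736	0.469098
-2.460914	0.335369	0.300565	0.525339
-2.408554	0.368928	0.333776	0.579078
-2.356194	0.400000	0.365692	0.629289
-2.303835	0.427977	0.395703	0.675053
-2.251475	0.452337	0.423283	0.715574
-2.199115	0.472654	0.447995	0.750203
-2.146755	0.488610	0.469510	0.778451
-2.094395	0.500000	0.487608	0.800000
-2.042035	0.506740	0.502186	0.814710
-1.989675	0.508864	0.513258	0.822622
-1.937315	0.506528	0.520953	0.823955
-1.884956	0.500000	0.525514	0.819098
-1.832596	0.489658	0.527287	0.808604
-1.780236	0.475975	0.526712	0.793171
-1.727876	0.459511	0.524314	0.773623
-1.675516	0.440898	0.520684	0.750894
-1.623156	0.420820	0.516468	0.725996
-1.570796	0.400000	0.512345	0.700000
-1.518436	0.379180	0.509009	0.674004
-1.466077	0.359102	0.507156	0.649106
-1.413717	0.340489	0.507459	0.626377
-1.361357	0.324025	0.510549	0.606829
-1.308997	0.310342	0.517006	0.591396
-1.256637	0.300000	0.527333	0.580902
-1.204277	0.293472	0.541948	0.576045
-1.151917	0.291136	0.561169	0.577378
-1.099557	0.293260	0.585208	0.585290
-1.047198	0.300000	0.614158	0.600000
-0.994838	0.311390	0.647994	0.621549
-0.942478	0.327346	0.686569	0.649797
-0.890118	0.347663	0.729617	0.684426
-0.837758	0.372023	0.776757	0.724947
-0.785398	0.400000	0.827502	0.770711
-0.733038	0.431072	0.881267	0.820922
-0.680678	0.464631	0.937380	0.874661
-0.628319	0.500000	0.995105	0.930902
-0.575959	0.536447	1.053646	0.988538
-0.523599	0.573205	1.112178	1.046410
-0.471239	0.609488	1.169853	1.103333
-0.418879	0.644512	1.225830	1.158123
-0.366519	0.677514	1.279288	1.209629
-0.314159	0.707768	1.329445	1.256758
-0.261799	0.734607	1.375578	1.298502
-0.209440	0.757433	1.417040	1.333964
-0.157080	0.775739	1.453269	1.362377
-0.104720	0.789116	1.483808	1.383126
-0.052360	0.797264	1.508311	1.395758
0.000000	0.800000	1.526550	1.400000
0.052360	0.797264	1.538420	1.395758
0.104720	0.789116	1.543945	1.383126
0.157080	0.775739	1.543267	1.362377
0.209440	0.757433	1.536653	1.333964
0.261799	0.734607	1.524480	1.298502
0.314159	0.707768	1.507226	1.256758
0.366519	0.677514	1.485461	1.209629
0.418879	0.644512	1.459830	1.158123
0.471239	0.609488	1.431039	1.103333
0.523599	0.573205	1.399833	1.046410
0.575959	0.536447	1.366983	0.988538
0.628319	0.500000	1.333264	0.930902
0.680678	0.464631	1.299435	0.874661
0.733038	0.431072	1.266224	0.820922
0.785398	0.400000	1.234308	0.770711
0.837758	0.372023	1.204297	0.724947
0.890118	0.347663	1.176717	0.684426
0.942478	0.327346	1.152005	0.649797
0.994838	0.311390	1.130490	0.621549
1.047198	0.300000	1.112392	0.600000
1.099557	0.293260	1.097814	0.585290
1.151917	0.291136	1.086742	0.577378
1.204277	0.293472	1.079047	0.576045
1.256637	0.300000	1.074486	0.580902
1.308997	0.310342	1.072713	0.591396
1.361357	0.324025	1.073288	0.606829
1.413717	0.340489	1.075686	0.626377
1.466077	0.359102	1.079316	0.649106
1.518436	0.379180	1.083532	0.674004
1.570796	0.400000	1.087655	0.700000
1.623156	0.420820	1.090991	0.725996
1.675516	0.440898	1.092844	0.750894
1.727876	0.459511	1.092541	0.773623
1.780236	0.475975	1.089451	0.793171
1.832596	0.489658	1.082994	0.808604
1.884956	0.500000	1.072667	0.819098
1.937315	0.506528	1.058052	0.823955
1.989675	0.508864	1.038831	0.822622
2.042035	0.506740	1.014792	0.814710
2.094395	0.500000	0.985842	0.800000
2.146755	0.488610	0.952006	0.778451
2.199115	0.472654	0.913431	0.750203
2.251475	0.452337	0.870383	0.715574
2.303835	0.427977	0.823243	0.675053
2.356194	0.400000	0.772498	0.629289
2.408554	0.368928	0.718733	0.579078
2.460914	0.335369	0.662620	0.525339
2.513274	0.300000	0.604895	0.469098
2.565634	0.263553	0.546354	0.411462
2.617994	0.226795	0.487822	0.353590
2.670354	0.190512	0.430147	0.296667
2.722714	0.155488	0.374170	0.241877
2.775074	0.122486	0.320712	0.190371
2.827433	0.092232	0.270555	0.143242
2.879793	0.065393	0.224422	0.101498
2.932153	0.042567	0.182960	0.066036
2.984513	0.024261	0.146731	0.037623
3.036873	0.010884	0.116192	0.016874
3.089233	0.002736	0.091689	0.004242
3.141593	0.000000	0.073450	0.000000
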