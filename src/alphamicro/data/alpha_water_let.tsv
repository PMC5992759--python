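# Alpha-particle LET (total stopping power) in liquid water.
# Generated from an ICRU-49-style proton electronic stopping table
# (liquid water) joined to Bethe theory at high energy, scaled to
# helium with the ZBL effective-charge parametrization
#   (z_eff/2)^2 = 1 - exp(-sum a_i x^i), x = ln(E/amu in keV).
# Columns: energy_kev let_kev_per_um
10	26.1708
10.579	27.3009
11.1916	28.4737
11.8396	29.69
12.5251	30.9509
13.2504	32.2573
14.0176	33.61
14.8293	35.0099
15.6879	36.4579
16.5963	37.9546
17.5572	39.501
18.5738	41.0976
19.6493	42.7454
20.7871	44.445
21.9907	46.1972
23.264	48.0027
24.611	49.8623
26.0361	51.7767
27.5436	53.7468
29.1385	55.7734
30.8256	57.8574
32.6105	59.9997
34.4988	62.2014
36.4963	64.4635
38.6095	66.7872
40.8451	69.1751
43.2102	71.6287
45.7121	74.1483
48.359	76.7356
51.1591	79.3925
54.1213	82.121
57.2551	84.9233
60.5703	87.8021
64.0774	90.7601
67.7877	93.8003
71.7128	96.9262
75.8651	100.142
80.2579	103.452
84.905	106.868
89.8212	110.388
95.0221	114.016
100.524	117.761
106.345	121.627
112.502	125.623
119.016	129.756
125.908	133.993
133.198	138.382
140.911	142.935
149.07	147.661
157.701	152.573
166.832	157.665
176.492	162.965
186.712	168.492
197.523	174.259
208.96	180.311
221.059	186.643
233.859	193.272
247.4	200.192
261.725	207.435
276.88	215.031
292.912	223.323
309.872	232.065
327.814	237.688
346.796	240.611
366.876	243.275
388.119	245.593
410.592	247.061
434.366	247.942
459.517	248.907
486.124	249.947
514.272	250.354
544.05	250.384
575.551	250.45
608.877	250.4
644.133	250.137
681.429	249.864
720.886	248.015
762.627	245.292
806.785	242.311
853.5	238.691
902.919	235.038
955.2	231.343
1010.51	226.826
1069.02	220.588
1130.92	214.397
1196.4	208.335
1265.68	203.414
1338.96	198.474
1416.49	193.629
1498.51	188.984
1585.28	184.319
1677.07	179.778
1774.17	175.231
1876.9	170.653
1985.58	166.08
2100.55	161.139
2222.18	156.25
2350.85	151.424
2486.97	146.44
2630.97	141.481
2783.31	136.628
2944.47	131.743
3114.96	126.99
3295.32	122.345
3486.13	117.826
3687.99	112.298
3901.53	106.124
4127.44	101.553
4366.43	97.7499
4500	95.769
4619.25	94.0802
4886.72	90.5414
5169.67	87.257
5469.01	84.1364
5486	83.9676
5785.68	81.1247
6120.68	77.9905
6475.08	74.7349
6850.01	71.6143
7246.64	68.6234
7666.24	65.7569
8110.13	63.0487
8579.73	60.5165
8784	59.4884
9076.51	58.086
9602.06	55.753
10158	53.4528
10746.2	51.1606
11368.5	48.9667
12026.7	46.8775
12723.1	44.9305
13459.8	43.0644
14239.1	41.2758
15063.6	39.5614
15935.8	37.911
16858.6	36.1993
17834.7	34.5648
18867.4	33.0041
19959.9	31.52
21115.6	30.1641
22338.2	28.8665
23631.7	27.6248
25000	26.3645
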