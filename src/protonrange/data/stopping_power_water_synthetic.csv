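energy_MeV,mass_stopping_MeV_cm2_g
0.1,852.691744
0.105929,848.454726
0.11221,842.021474
0.118863,833.651141
0.12591,823.580752
0.133376,812.026864
0.141284,799.187121
0.14966,785.241687
0.158534,770.354586
0.167934,754.674946
0.17789,738.338151
0.188438,721.46691
0.19961,704.172258
0.211445,686.55447
0.223982,668.703928
0.237262,650.701902
0.25133,632.6213
0.266231,614.527337
0.282017,596.478178
0.298738,578.525517
0.31645,560.715121
0.335213,543.087331
0.355088,525.677525
0.376141,508.516553
0.398443,491.631123
0.422067,475.044177
0.447092,458.775226
0.4736,442.840659
0.501681,427.254036
0.531426,412.026351
0.562934,397.166278
0.596311,382.680394
0.631667,368.573389
0.669119,354.848255
0.708792,341.506463
0.750817,328.548123
0.795334,315.972131
0.84249,303.776305
0.892442,291.957511
0.945356,280.511772
1.001407,269.434379
1.060781,258.719977
1.123676,248.36266
1.190299,238.356044
1.260873,228.693343
1.335632,219.367428
1.414823,210.370895
1.498709,201.696112
1.587569,193.335268
1.681697,185.28042
1.781407,177.523531
1.887028,170.056505
1.998911,162.871216
2.117429,155.959545
2.242973,149.313393
2.375961,142.924715
2.516834,136.785534
2.66606,130.887957
2.824133,125.224196
2.991578,119.786576
3.168952,114.567549
3.356842,109.559703
3.555872,104.755774
3.766703,100.148645
3.990035,95.73136
4.226608,91.497125
4.477207,87.43931
4.742665,83.551455
5.023862,79.827271
5.321732,76.260639
5.637262,72.845615
5.971501,69.576424
6.325557,66.447463
6.700605,63.453301
7.097891,60.588675
7.518731,57.848488
7.964524,55.227809
8.436748,52.721869
8.936971,50.326058
9.466852,48.035922
10.028151,45.847164
10.62273,43.755632
11.252561,41.757326
11.919736,39.848387
12.626469,38.025095
13.375104,36.283869
14.168127,34.62126
15.008168,33.033947
15.898017,31.518735
16.840625,30.072552
17.839122,28.692444
18.89682,27.375569
20.017231,26.1192
21.204071,24.920716
22.461281,23.777598
23.793031,22.687431
25.203743,21.647896
26.698097,20.656767
28.281052,19.71191
29.957862,18.811278
31.734092,17.952908
33.615637,17.13492
35.60874,16.355511
37.720016,15.612954
39.956471,14.905595
42.325528,14.231851
44.835049,13.590204
47.493361,12.979203
50.309288,12.397459
53.292173,11.843643
56.451917,11.316483
59.799004,10.814763
63.344544,10.33732
67.100302,9.883042
71.078742,9.450866
75.293068,9.039777
79.757266,8.648803
84.486149,8.277018
89.495413,7.923536
94.801681,7.587511
100.422562,7.268135
106.376711,6.964637
112.683887,6.67628
119.365022,6.402363
126.442287,6.142215
133.93917,5.895197
141.88055,5.660699
150.292782,5.438138
159.203784,5.22696
168.643127,5.026637
178.642138,4.836664
189.233999,4.656561
200.453862,4.485869
212.338962,4.324153
224.92874,4.170998
238.264978,4.026007
252.391934,3.888803
267.356491,3.759027
283.208311,3.636339
300.0,3.520412
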