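energy_MeV,sigma_mb
5.66,0.0
6.0,0.5845
6.5,1.8842
7.0,3.6364
7.5,5.7593
8.0,8.1689
8.5,10.7797
9.0,13.5047
9.5,16.2558
10.0,18.9436
10.5,21.4781
11.0,23.7686
11.5,25.7235
12.0,27.251
12.5,28.2586
13.0,28.6537
13.5,27.3558
14.0,26.1228
15.0,23.8406
16.0,21.7859
17.0,19.9382
18.0,18.2784
20.0,15.4521
22.0,13.1797
24.0,11.3555
26.0,9.8924
28.0,8.7196
30.0,7.7798
32.0,7.027
35.0,6.1691
37.5,5.6431
40.0,5.2446
45.0,4.7141
50.0,4.4097
60.0,4.1349
80.0,4.0146
100.0,4.0016
150.0,4.0
200.0,4.0
250.0,4.0
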