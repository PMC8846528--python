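energy_MeV,sigma_mb
20.61,0.0
23.0,10.0
26.0,30.0
30.0,55.0
35.0,75.0
40.0,88.0
45.0,90.0
50.0,87.0
60.0,80.0
70.0,74.0
80.0,70.0
100.0,62.0
150.0,52.0
200.0,47.0
250.0,45.0
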