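energy_MeV,sigma_mb
16.79,0.0
19.0,15.0
22.0,40.0
25.0,60.0
28.0,68.0
32.0,65.0
40.0,55.0
50.0,48.0
60.0,44.0
80.0,40.0
100.0,38.0
150.0,35.0
250.0,33.0
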